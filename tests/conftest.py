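"""Shared fixtures and the independent likelihood-maximisation oracle used
to validate the EM phaser."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from hapburden.io_formats import Marker, MarkerPanel
from hapburden.phasing import enumerate_pairs


@pytest.fixture
def panel3() -> MarkerPanel:
    """Three-marker toy panel (two SNPs + one deletion)."""
    return MarkerPanel(
        markers=(
            Marker("m1", "G", "A", False, 100),
            Marker("m2", "C", "T", False, 200),
            Marker("m3", "C", "-", True, 300),
        )
    )


@pytest.fixture
def panel10() -> MarkerPanel:
    from hapburden.reference import DEFAULT_PANEL

    return DEFAULT_PANEL


# ---------------------------------------------------------------------------
# Brute-force maximum-likelihood oracle (independent of the EM path)
# ---------------------------------------------------------------------------


def _pair_lists(rows: np.ndarray):
    """Candidate haplotype index set + per-genotype compatible pair arrays."""
    hap_index: dict[tuple, int] = {}
    per_row = []
    for row in rows:
        pairs = enumerate_pairs(row)
        ii, jj = [], []
        for a, b in pairs:
            for h in (a, b):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            ii.append(hap_index[a])
            jj.append(hap_index[b])
        ii = np.array(ii)
        jj = np.array(jj)
        per_row.append((ii, jj, np.where(ii == jj, 1.0, 2.0)))
    haps = [None] * len(hap_index)
    for h, k in hap_index.items():
        haps[k] = h
    return haps, per_row


def oracle_loglik(freqs: np.ndarray, per_row) -> float:
    ll = 0.0
    for ii, jj, mult in per_row:
        ll += np.log((mult * freqs[ii] * freqs[jj]).sum())
    return float(ll)


def _neg_ll_and_grad(f: np.ndarray, per_row) -> tuple[float, np.ndarray]:
    f = np.clip(f, 1e-300, None)
    ll = 0.0
    grad = np.zeros_like(f)
    for ii, jj, mult in per_row:
        contrib = mult * f[ii] * f[jj]
        # floor the pattern probability so starts that zero out an observed
        # genotype yield a large-but-finite penalty instead of -inf
        s = max(contrib.sum(), 1e-300)
        ll += np.log(s)
        np.add.at(grad, ii, mult * f[jj] / s)
        np.add.at(grad, jj, mult * f[ii] / s)
    return -float(ll), -grad


def oracle_freqs(rows: np.ndarray, seed: int = 0):
    """Maximise the observed-data likelihood by direct constrained search.

    Runs SLSQP on the frequency simplex with the analytic gradient from
    many deterministic starts — an optimisation route entirely independent
    of the EM iteration, and able to land exactly on boundary optima.
    Returns ``(haplotype alt-mask list, frequency vector, log-likelihood,
    spread)`` where *spread* is the largest total-variation distance between
    near-optimal solutions found from different starts (log-likelihood
    within 1e-6 of the best).  A large spread flags a non-identified
    instance: the likelihood has a flat optimum set and the frequency
    vector is not estimable there.
    """
    haps, per_row = _pair_lists(rows)
    K = len(haps)
    if K == 1:
        one = np.array([1.0])
        return haps, one, oracle_loglik(one, per_row), 0.0

    rng = np.random.default_rng(seed)
    starts = [np.full(K, 1.0 / K)]
    starts += [rng.dirichlet(np.ones(K)) for _ in range(8)]
    starts += [rng.dirichlet(np.full(K, 0.3)) for _ in range(4)]
    solutions = []
    for x0 in starts:
        res = minimize(
            lambda f: _neg_ll_and_grad(f, per_row),
            x0,
            jac=True,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * K,
            constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0}],
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        f = np.clip(res.x, 0.0, None)
        f = f / f.sum()
        solutions.append((f, oracle_loglik(np.clip(f, 1e-300, None), per_row)))
    best_f, best_ll = max(solutions, key=lambda t: t[1])
    near = [f for f, ll in solutions if ll >= best_ll - 1e-6]
    spread = max(
        (0.5 * float(np.abs(f - best_f).sum()) for f in near), default=0.0
    )
    return haps, best_f, best_ll, spread


def random_instance(panel: MarkerPanel, rng: np.random.Generator, n_max: int = 20):
    """Random unphased cohort drawn from a Dirichlet haplotype distribution."""
    n_markers = len(panel)
    masks = [
        tuple((h >> k) & 1 for k in range(n_markers)) for h in range(2**n_markers)
    ]
    freqs = rng.dirichlet(np.ones(len(masks)))
    n = int(rng.integers(8, n_max + 1))
    draws = rng.choice(len(masks), size=(n, 2), p=freqs)
    rows = np.array(
        [[masks[a][k] + masks[b][k] for k in range(n_markers)] for a, b in draws],
        dtype=np.int8,
    )
    return rows


def identified_instance(panel: MarkerPanel, rng: np.random.Generator, seed: int):
    """Random instance conditioned on an identified (unique) MLE.

    Frequency estimates can only be compared to an oracle where the
    maximiser is unique; instances whose multi-start oracle finds distinct
    equal-likelihood maximisers (flat ridge) are redrawn.  Returns
    ``(rows, haps, f_oracle, ll_oracle)``.
    """
    while True:
        rows = random_instance(panel, rng)
        haps, f, ll, spread = oracle_freqs(rows, seed=seed)
        if spread <= 5e-5:
            return rows, haps, f, ll
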