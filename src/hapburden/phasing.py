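"""Haplotype frequency estimation and diplotype assignment by EM.

Unphased multilocus genotypes over a tightly linked biallelic panel are
phased with the classic expectation-maximisation estimator for haplotype
frequencies under random mating (gene counting generalised to multilocus
data).  The observed-data likelihood of an individual with genotype *g* is

    P(g | f) = sum over compatible diplotypes {h1, h2} of
               (2 - delta_{h1 h2}) * f_{h1} * f_{h2}

and EM alternates expected diplotype counts (E-step) with frequency updates
f_h = expected count of h / 2n (M-step).  The estimator is deterministic:
the fixed-point iteration is accelerated by safeguarded SQUAREM and run
from a fixed list of initialisations (allele-frequency product, uniform,
seeded Dirichlet draws), so identical input always yields identical
output.  The coalescent prior and MCMC machinery of full Bayesian phasers
are deliberately out of scope — at the scale of a single haplotype block the
estimand (the haplotype frequency vector) is the same.

Individuals with any missing genotype are excluded before the EM with a
logged count; no imputation is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hapburden.io_formats import GenotypeMatrix, MISSING

logger = logging.getLogger(__name__)

AltMask = tuple[int, ...]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplotypeFreq:
    hap_id: str
    allele_string: str
    freq_case: float
    freq_control: float
    freq_pooled: float


@dataclass
class HaplotypeFreqTable:
    """Estimated haplotype frequencies, pooled and per cohort.

    Entries are kept in lexicographic order of allele string, matching the
    H1..Hk labelling convention of :func:`label_haplotypes`.
    """

    entries: list[HaplotypeFreq]

    def __post_init__(self) -> None:
        ids = [e.hap_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("hap_ids must be unique")
        strings = [e.allele_string for e in self.entries]
        if len(set(map(len, strings))) > 1:
            raise ValueError("allele strings must all have the panel's length")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def by_id(self, hap_id: str) -> HaplotypeFreq:
        for e in self.entries:
            if e.hap_id == hap_id:
                return e
        raise KeyError(hap_id)

    def by_string(self, allele_string: str) -> HaplotypeFreq:
        for e in self.entries:
            if e.allele_string == allele_string:
                return e
        raise KeyError(allele_string)

    def common_ids(self, threshold: float = 0.005) -> list[str]:
        """Haplotype ids with pooled frequency strictly above *threshold*."""
        return [e.hap_id for e in self.entries if e.freq_pooled > threshold]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hap_id": [e.hap_id for e in self.entries],
                "allele_string": [e.allele_string for e in self.entries],
                "freq_case": [e.freq_case for e in self.entries],
                "freq_control": [e.freq_control for e in self.entries],
                "freq_pooled": [e.freq_pooled for e in self.entries],
            }
        )


@dataclass(frozen=True)
class DiplotypeAssignment:
    sample_id: str
    cohort: str
    hap1: str  # hap_id; pair ordered so that allele_string(hap1) <= allele_string(hap2)
    hap2: str
    posterior: float


@dataclass
class PhasedCohort:
    """Maximum-posterior diplotype per individual plus EM diagnostics."""

    assignments: list[DiplotypeAssignment]
    log_likelihood: float
    n_iter: int
    converged: bool
    n_excluded_missing: int = 0

    def __len__(self) -> int:
        return len(self.assignments)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [a.sample_id for a in self.assignments],
                "cohort": [a.cohort for a in self.assignments],
                "hap1": [a.hap1 for a in self.assignments],
                "hap2": [a.hap2 for a in self.assignments],
                "posterior": [a.posterior for a in self.assignments],
            }
        )


# ---------------------------------------------------------------------------
# Diplotype enumeration
# ---------------------------------------------------------------------------


def enumerate_pairs(genotype: "list[int] | np.ndarray") -> list[tuple[AltMask, AltMask]]:
    """All diplotypes compatible with an unphased biallelic genotype.

    *genotype* is the per-marker alternative-allele dosage (0, 1 or 2; no
    missing values).  Haplotypes are returned as alt-indicator tuples, each
    pair sorted so that ``pair[0] <= pair[1]``; the list contains
    ``2^(h-1)`` distinct diplotypes for *h* heterozygous markers (one when
    *h* = 0), because the assignment at the first heterozygous marker can be
    fixed without loss of generality.
    """
    genotype = list(int(g) for g in genotype)
    if any(g not in (0, 1, 2) for g in genotype):
        raise ValueError("genotype must be fully observed (dosages in {0,1,2})")
    het = [i for i, g in enumerate(genotype) if g == 1]
    base = [g // 2 for g in genotype]  # 0 for dose 0/1, 1 for dose 2
    pairs: list[tuple[AltMask, AltMask]] = []
    if not het:
        h = tuple(base)
        return [(h, h)]
    # fix the first het marker: hap A carries ref there
    for bits in range(2 ** (len(het) - 1)):
        a = base.copy()
        b = base.copy()
        b[het[0]] = 1
        for k, m in enumerate(het[1:], start=0):
            if (bits >> k) & 1:
                a[m] = 1
            else:
                b[m] = 1
        pa, pb = tuple(a), tuple(b)
        pairs.append((pa, pb) if pa <= pb else (pb, pa))
    return pairs


# ---------------------------------------------------------------------------
# EM estimator
# ---------------------------------------------------------------------------


def em_estimate(
    gm: GenotypeMatrix,
    tol: float = 1e-8,
    max_iter: int = 1000,
    prune_threshold: float = 1e-7,
    n_starts: int = 10,
) -> tuple[HaplotypeFreqTable, PhasedCohort]:
    """Estimate haplotype frequencies and assign diplotypes by EM.

    Returns the frequency table (pooled and per-cohort columns, labelled
    H1..Hk in lexicographic order of allele string) and the per-individual
    maximum-posterior diplotype under the final frequencies.  Ties between
    equal-posterior diplotypes are broken by lexicographic order of the
    sorted pair of allele strings.  Per-cohort frequencies are the expected
    haplotype counts of that cohort's individuals (final E-step) divided by
    twice the cohort size.

    The EM map is run from ``n_starts`` deterministic initialisations (the
    per-marker allele-frequency product, the uniform vector, and Dirichlet
    draws from a hard-coded seed) and the highest-likelihood stationary
    point is kept; ``n_iter`` reports the total EM-map applications across
    starts.

    Raises ``ValueError`` if no individual remains after excluding those
    with missing genotypes; failure to converge within *max_iter* returns
    with ``converged=False`` and a logged warning.
    """
    keep = ~gm.has_missing()
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning(
            "excluding %d individual(s) with missing genotypes before EM", n_excluded
        )
    dosage = gm.dosage[keep]
    sample_ids = [s for s, k in zip(gm.sample_ids, keep) if k]
    cohorts = [c for c, k in zip(gm.cohorts, keep) if k]
    n = len(sample_ids)
    if n == 0:
        raise ValueError("no individuals remain after missing-genotype exclusion")

    patterns, inverse = np.unique(dosage, axis=0, return_inverse=True)
    n_pat = patterns.shape[0]
    w_case = np.zeros(n_pat)
    w_ctrl = np.zeros(n_pat)
    for idx, cohort in zip(inverse, cohorts):
        if cohort == "case":
            w_case[idx] += 1
        else:
            w_ctrl[idx] += 1
    w_all = w_case + w_ctrl

    # global haplotype index over all compatible haplotypes
    hap_index: dict[AltMask, int] = {}
    pat_pairs: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for p in range(n_pat):
        pairs = enumerate_pairs(patterns[p])
        ii, jj = [], []
        for a, b in pairs:
            for h in (a, b):
                if h not in hap_index:
                    hap_index[h] = len(hap_index)
            ii.append(hap_index[a])
            jj.append(hap_index[b])
        ii = np.array(ii, dtype=np.intp)
        jj = np.array(jj, dtype=np.intp)
        mult = np.where(ii == jj, 1.0, 2.0)
        pat_pairs.append((ii, jj, mult))
    haps = [None] * len(hap_index)
    for h, i in hap_index.items():
        haps[i] = h
    K = len(haps)

    # primary start: product of per-marker observed allele frequencies
    af = dosage.mean(axis=0) / 2.0
    f0 = np.empty(K)
    for i, h in enumerate(haps):
        f0[i] = float(np.prod([af[j] if a else 1.0 - af[j] for j, a in enumerate(h)]))
    total = f0.sum()
    if total <= 0:  # pragma: no cover - cannot happen for compatible haplotypes
        f0 = np.full(K, 1.0 / K)
    else:
        f0 /= total

    def em_map(fv: np.ndarray) -> tuple[np.ndarray, float]:
        """One application of the EM fixed-point map; also returns ll(fv)."""
        ll_ = 0.0
        counts = np.zeros(K)
        for p in range(n_pat):
            ii, jj, mult = pat_pairs[p]
            probs = mult * fv[ii] * fv[jj]
            s = probs.sum()
            if s <= 0.0:  # fv assigns probability 0 to an observed genotype
                return fv, -math.inf
            ll_ += w_all[p] * math.log(s)
            post = probs / s
            np.add.at(counts, ii, w_all[p] * post)
            np.add.at(counts, jj, w_all[p] * post)
        f_new = counts / (2.0 * n)
        assert abs(f_new.sum() - 1.0) < 1e-9 and (f_new >= 0).all()
        return f_new, ll_

    def check_monotone(ll_new: float, ll_old: float) -> None:
        # EM guarantees a monotone likelihood; tolerate only float round-off
        if ll_new < ll_old - 1e-9 * max(1.0, abs(ll_old)):
            raise AssertionError(
                f"log-likelihood decreased: {ll_old} -> {ll_new}"
            )

    def run_em(f: np.ndarray) -> tuple[np.ndarray, float, int, bool]:
        """Safeguarded SQUAREM acceleration of the EM map from one start.

        Each cycle takes two plain EM steps, extrapolates along the
        fixed-point residual, and falls back to the plain double step
        whenever the extrapolated point does not improve the likelihood —
        preserving EM's monotonicity while converging superlinearly on the
        near-flat ridges where plain EM crawls.  Iterations count EM-map
        applications.
        """
        prev_ll = -math.inf
        it = 0
        while it < max_iter:
            f1, ll0 = em_map(f)
            it += 1
            check_monotone(ll0, prev_ll)
            if abs(ll0 - prev_ll) < tol:
                return f1, ll0, it, True
            f2, ll1 = em_map(f1)
            it += 1
            check_monotone(ll1, ll0)
            if abs(ll1 - ll0) < tol:
                return f2, ll1, it, True
            r = f1 - f
            v = (f2 - f1) - r
            nv = float(np.linalg.norm(v))
            accepted = False
            if nv > 0 and it < max_iter:
                alpha = -float(np.linalg.norm(r)) / nv
                f_acc = f - 2.0 * alpha * r + alpha * alpha * v
                f_acc = np.clip(f_acc, 1e-16, None)
                f_acc /= f_acc.sum()
                f3, ll_acc = em_map(f_acc)
                it += 1
                if ll_acc >= ll1:  # safeguard: accept only if not worse
                    check_monotone(ll_acc, ll1)
                    f = f3
                    prev_ll = ll_acc
                    accepted = True
            if not accepted:
                f = f2
                prev_ll = ll1
        return f, prev_ll, it, False

    # Deterministic multistart: the product-of-allele-frequency start can
    # land in a local optimum of the multilocus likelihood, so it is
    # complemented by the uniform start and a fixed set of Dirichlet draws
    # from a hard-coded seed.  The start list depends only on the data, so
    # identical input still yields identical output.
    starts = [f0, np.full(K, 1.0 / K)]
    start_rng = np.random.default_rng(1729)
    starts += [start_rng.dirichlet(np.ones(K)) for _ in range(max(0, n_starts - 2))]
    f = starts[0]
    best_ll = -math.inf
    it_total = 0
    converged = False
    for f_init in starts:
        f_run, ll_run, it_run, conv_run = run_em(np.asarray(f_init, dtype=float))
        it_total += it_run
        if ll_run > best_ll:
            best_ll = ll_run
            f = f_run
            converged = conv_run
    it = it_total
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)

    n_case = sum(c == "case" for c in cohorts)
    n_ctrl = n - n_case
    panel = gm.panel
    hap_strings = [panel.haplotype_string(h) for h in haps]
    # final per-cohort expected counts under the final frequencies
    counts_case = np.zeros(K)
    counts_ctrl = np.zeros(K)
    best_pair: list[tuple[int, int]] = []
    best_post: list[float] = []
    ll = 0.0  # log-likelihood at the final frequencies
    for p in range(n_pat):
        ii, jj, mult = pat_pairs[p]
        probs = mult * f[ii] * f[jj]
        s = probs.sum()
        ll += w_all[p] * math.log(s)
        post = probs / s
        if w_case[p]:
            np.add.at(counts_case, ii, w_case[p] * post)
            np.add.at(counts_case, jj, w_case[p] * post)
        if w_ctrl[p]:
            np.add.at(counts_ctrl, ii, w_ctrl[p] * post)
            np.add.at(counts_ctrl, jj, w_ctrl[p] * post)
        # maximum-posterior pair, ties broken lexicographically on the
        # sorted pair of allele strings
        pmax = post.max()
        cand = [k for k in range(len(ii)) if post[k] >= pmax * (1.0 - 1e-12)]
        kbest = min(
            cand, key=lambda k: tuple(sorted((hap_strings[ii[k]], hap_strings[jj[k]])))
        )
        a, b = sorted(
            (int(ii[kbest]), int(jj[kbest])), key=lambda x: hap_strings[x]
        )
        best_pair.append((a, b))
        best_post.append(float(post[kbest]))

    freq_case = counts_case / (2.0 * n_case) if n_case else np.zeros(K)
    freq_ctrl = counts_ctrl / (2.0 * n_ctrl) if n_ctrl else np.zeros(K)

    # haplotypes referenced by an assignment are never pruned
    used = set()
    for a, b in best_pair:
        used.add(a)
        used.add(b)
    keep_hap = [i for i in range(K) if f[i] >= prune_threshold or i in used]

    strings = {i: hap_strings[i] for i in keep_hap}
    order = sorted(keep_hap, key=lambda i: strings[i])
    labels = {i: f"H{r + 1}" for r, i in enumerate(order)}

    table = HaplotypeFreqTable(
        entries=[
            HaplotypeFreq(
                hap_id=labels[i],
                allele_string=strings[i],
                freq_case=float(freq_case[i]),
                freq_control=float(freq_ctrl[i]),
                freq_pooled=float(f[i]),
            )
            for i in order
        ]
    )
    assignments = []
    for s_idx, (sid, cohort) in enumerate(zip(sample_ids, cohorts)):
        p = inverse[s_idx]
        a, b = best_pair[p]
        assignments.append(
            DiplotypeAssignment(
                sample_id=sid,
                cohort=cohort,
                hap1=labels[a],
                hap2=labels[b],
                posterior=best_post[p],
            )
        )
    phased = PhasedCohort(
        assignments=assignments,
        log_likelihood=float(ll),
        n_iter=it,
        converged=converged,
        n_excluded_missing=n_excluded,
    )
    return table, phased


def write_freq_table(ft: HaplotypeFreqTable, path) -> None:
    """Write a frequency table TSV (hap_id, allele_string, freq_case,
    freq_control, freq_pooled)."""
    ft.to_dataframe().to_csv(path, sep="\t", index=False)


def read_freq_table(path) -> HaplotypeFreqTable:
    df = pd.read_csv(path, sep="\t", dtype={"hap_id": str, "allele_string": str})
    return HaplotypeFreqTable(
        entries=[
            HaplotypeFreq(
                hap_id=row.hap_id,
                allele_string=row.allele_string,
                freq_case=float(row.freq_case),
                freq_control=float(row.freq_control),
                freq_pooled=float(row.freq_pooled),
            )
            for row in df.itertuples()
        ]
    )


def write_phased(pc: PhasedCohort, path) -> None:
    """Write per-individual diplotype assignments as TSV."""
    pc.to_dataframe().to_csv(path, sep="\t", index=False)


def read_phased(path) -> PhasedCohort:
    """Read assignments written by :func:`write_phased`.

    EM diagnostics (log-likelihood, iteration count) are not round-tripped;
    they are set to neutral values.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    assignments = [
        DiplotypeAssignment(
            sample_id=row.sample_id,
            cohort=row.cohort,
            hap1=row.hap1,
            hap2=row.hap2,
            posterior=float(row.posterior),
        )
        for row in df.itertuples()
    ]
    return PhasedCohort(
        assignments=assignments, log_likelihood=float("nan"), n_iter=0, converged=True
    )


def label_haplotypes(ft: HaplotypeFreqTable) -> HaplotypeFreqTable:
    """Relabel haplotypes H1..Hk in lexicographic order of allele string.

    Idempotent and stable across runs; the ordering of entries follows the
    labels.
    """
    strings = [e.allele_string for e in ft.entries]
    if len(set(strings)) != len(strings):
        raise ValueError("allele strings must be unique for labelling")
    order = sorted(ft.entries, key=lambda e: e.allele_string)
    return HaplotypeFreqTable(
        entries=[
            HaplotypeFreq(
                hap_id=f"H{r + 1}",
                allele_string=e.allele_string,
                freq_case=e.freq_case,
                freq_control=e.freq_control,
                freq_pooled=e.freq_pooled,
            )
            for r, e in enumerate(order)
        ]
    )
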