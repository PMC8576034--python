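"""Case-control association statistics on 2x2 allele-count tables.

Phased haplotypes are converted to biallelic presence/absence markers (one
dosage column per haplotype) and each haplotype is tested against all
others pooled, exactly as a biallelic allele-count test:

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),   N = a+b+c+d, 1 df
    OR   = (a d) / (b c)
    95% CI = exp( ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d) )   (Woolf)

where a/b are case alt/ref allele counts and c/d the control counts.  No
continuity correction is applied by default (Yates' correction is available
behind a flag); the same statistic backs the gene-level burden test.
Undefined quantities (zero cells, empty margins, boundary frequencies) are
returned as NaN rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist

from hapburden.phasing import HaplotypeFreqTable, PhasedCohort

NA = float("nan")


@dataclass(frozen=True)
class Assoc2x2Result:
    """Pearson chi-square / odds-ratio summary of one 2x2 allele table."""

    a: float  # case alt count
    b: float  # case ref count
    c: float  # control alt count
    d: float  # control ref count
    chi2: float
    p: float
    or_: float
    ci_low: float
    ci_high: float
    maf_case: float
    maf_control: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.chi2)


def assoc_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> Assoc2x2Result:
    """Pearson chi-square (1 df), odds ratio and Woolf 95% CI for a 2x2 table.

    Rows are cohorts (case, control), columns alleles (alt, ref).  If either
    column margin (a+c or b+d) or row margin is zero the whole test is
    undefined (all statistics NaN).  If any single cell is zero the odds
    ratio and its CI are NaN while chi-square and p are still computed.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    n_case = a + b
    n_ctrl = c + d
    maf_case = a / n_case if n_case > 0 else NA
    maf_ctrl = c / n_ctrl if n_ctrl > 0 else NA
    if n_case == 0 or n_ctrl == 0 or (a + c) == 0 or (b + d) == 0:
        return Assoc2x2Result(a, b, c, d, NA, NA, NA, NA, NA, maf_case, maf_ctrl)
    n = a + b + c + d
    num = abs(a * d - b * c)
    if yates:
        num = max(0.0, num - n / 2.0)
    chi2 = n * num * num / (n_case * n_ctrl * (a + c) * (b + d))
    p = float(_chi2_dist.sf(chi2, 1))
    if min(a, b, c, d) == 0:
        or_, lo, hi = NA, NA, NA
    else:
        or_ = (a * d) / (b * c)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(or_) - 1.96 * se)
        hi = math.exp(math.log(or_) + 1.96 * se)
    return Assoc2x2Result(a, b, c, d, chi2, p, or_, lo, hi, maf_case, maf_ctrl)


def assoc_from_freqs(f_case: float, f_control: float) -> float:
    """Odds ratio parameterised by cohort allele frequencies.

    OR = (f1/(1-f1)) / (f2/(1-f2)); agrees with :func:`assoc_2x2` whenever
    the counts are exactly f * 2N.  Returns NaN at the boundaries f in {0, 1}.
    """
    if not (0.0 <= f_case <= 1.0 and 0.0 <= f_control <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    if f_case in (0.0, 1.0) or f_control in (0.0, 1.0):
        return NA
    return (f_case / (1.0 - f_case)) / (f_control / (1.0 - f_control))


def haplotypes_to_biallelic(pc: PhasedCohort, ft: HaplotypeFreqTable) -> pd.DataFrame:
    """Per-haplotype copy-number (0/1/2) matrix from hard diplotype calls.

    Returns a DataFrame indexed by sample_id with one column per haplotype
    id; every row sums to 2 (each individual carries exactly two haplotype
    copies).
    """
    hap_ids = [e.hap_id for e in ft.entries]
    idx = {h: k for k, h in enumerate(hap_ids)}
    mat = np.zeros((len(pc.assignments), len(hap_ids)), dtype=np.int8)
    sample_ids = []
    for i, asn in enumerate(pc.assignments):
        for h in (asn.hap1, asn.hap2):
            if h not in idx:
                raise KeyError(f"assignment references unknown haplotype {h}")
            mat[i, idx[h]] += 1
        sample_ids.append(asn.sample_id)
    return pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"), columns=hap_ids)


def dosage_matrix_from_pairs(
    pairs: "list[tuple[str, str]]", sample_ids: "list[str]"
) -> pd.DataFrame:
    """Copy-number matrix directly from (hap, hap) string pairs.

    Convenience for working with simulated ground-truth diplotypes without
    running the EM; columns are the distinct haplotype strings observed.
    """
    haps = sorted({h for p in pairs for h in p})
    idx = {h: k for k, h in enumerate(haps)}
    mat = np.zeros((len(pairs), len(haps)), dtype=np.int8)
    for i, (h1, h2) in enumerate(pairs):
        mat[i, idx[h1]] += 1
        mat[i, idx[h2]] += 1
    return pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"), columns=haps)


def haplotype_assoc_scan(
    dosages: pd.DataFrame,
    cohorts: "list[str] | pd.Series",
    bonferroni: bool = False,
) -> list[tuple[str, Assoc2x2Result]]:
    """Allele-count association test for every haplotype column.

    For haplotype h: a = total copies of h among cases, b = 2 n_case - a,
    and likewise c/d for controls.  Rows are sorted by p-value (undefined
    tests last).  With ``bonferroni=True`` each p-value is multiplied by the
    number of defined tests (capped at 1) before sorting; raw p-values are
    the default, so no multiple-testing adjustment is applied unless asked.
    """
    cohorts = list(cohorts)
    is_case = np.array([c == "case" for c in cohorts])
    n_case = int(is_case.sum())
    n_ctrl = len(cohorts) - n_case
    results: list[tuple[str, Assoc2x2Result]] = []
    for hap in dosages.columns:
        col = dosages[hap].to_numpy()
        a = int(col[is_case].sum())
        c = int(col[~is_case].sum())
        b = 2 * n_case - a
        d = 2 * n_ctrl - c
        results.append((hap, assoc_2x2(a, b, c, d)))
    if bonferroni:
        m = sum(1 for _, r in results if not math.isnan(r.p))
        adjusted = []
        for hap, r in results:
            p_adj = min(1.0, r.p * m) if not math.isnan(r.p) else NA
            adjusted.append(
                (
                    hap,
                    Assoc2x2Result(
                        r.a, r.b, r.c, r.d, r.chi2, p_adj, r.or_,
                        r.ci_low, r.ci_high, r.maf_case, r.maf_control,
                    ),
                )
            )
        results = adjusted
    results.sort(key=lambda t: (math.isnan(t[1].p), t[1].p if not math.isnan(t[1].p) else 0.0, t[0]))
    return results


def scan_to_dataframe(scan: "list[tuple[str, Assoc2x2Result]]") -> pd.DataFrame:
    """Tabular view of a haplotype scan with percent-scale frequencies."""
    return pd.DataFrame(
        {
            "hap_id": [h for h, _ in scan],
            "a": [r.a for _, r in scan],
            "b": [r.b for _, r in scan],
            "c": [r.c for _, r in scan],
            "d": [r.d for _, r in scan],
            "maf_case_pct": [100 * r.maf_case for _, r in scan],
            "maf_control_pct": [100 * r.maf_control for _, r in scan],
            "chi2": [r.chi2 for _, r in scan],
            "p": [r.p for _, r in scan],
            "OR": [r.or_ for _, r in scan],
            "ci_low": [r.ci_low for _, r in scan],
            "ci_high": [r.ci_high for _, r in scan],
        }
    )


def pairwise_r2(alleles1: "np.ndarray | list[int]", alleles2: "np.ndarray | list[int]") -> float:
    """Squared allelic correlation r^2 between two biallelic markers.

    Inputs are parallel 0/1 allele indicator vectors over a pool of phased
    haplotype copies (not genotypes).  r^2 = D^2 / (p1 q1 p2 q2) with
    D = P(11) - p1 p2.  Returns NaN if either marker is monomorphic in the
    pool.
    """
    x = np.asarray(alleles1, dtype=float)
    y = np.asarray(alleles2, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise ValueError("allele vectors must be equal-length 1-D arrays")
    p1 = x.mean()
    p2 = y.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        return NA
    d = (x * y).mean() - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))
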