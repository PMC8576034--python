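"""LOF classification, co-segregation scan and gene-level burden test.

The qualifying-variant definition follows the study design being emulated:
variants annotated ``exonic``, ``UTR`` (including UTR3/UTR5), ``splicing``
or ``upstream`` count as loss-of-function.  This is broader than the usual
LOF definition (stop-gain/frameshift/essential splice); the mapping is a
configurable parameter precisely because it is unconventional.

The burden test collapses each gene's qualifying sites into cohort-level
allele observations: alt = sum of alt dosages over LOF sites x cohort
samples, ref = 2 x n_cohort x n_sites - alt, then applies the Pearson 2x2
chi-square / odds ratio of :mod:`hapburden.hapassoc`.  Genes with fewer
than two LOF sites are reported but not tested.  No zero-cell correction
is applied by default (a Haldane-Anscombe +0.5 option exists) and raw
p-values are reported (Bonferroni optional).

The co-segregation scan flags sites whose alt-dosage vector equals the
target haplotype's copy-number vector exactly across all sequenced
samples; an empty result is a valid outcome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from hapburden.hapassoc import Assoc2x2Result, assoc_2x2
from hapburden.io_formats import VariantTable

logger = logging.getLogger(__name__)

#: Functional categories that qualify as LOF (matched case-insensitively).
DEFAULT_LOF_CATEGORIES = frozenset(
    {"exonic", "utr", "utr3", "utr5", "splicing", "upstream"}
)


@dataclass(frozen=True)
class GeneBurdenRow:
    """Per-gene collapsed allele counts and (if tested) the 2x2 result."""

    gene: str
    n_lof_sites: int
    alt_case: int
    ref_case: int
    alt_control: int
    ref_control: int
    result: Assoc2x2Result | None  # None when n_lof_sites < 2 (untested)


@dataclass(frozen=True)
class CosegHit:
    """A site whose dosage tracks the target haplotype exactly."""

    site_id: str
    gene: str
    target_hap: str
    match_type: str = "exact_dosage"


def classify_lof(
    vt: VariantTable,
    categories: "frozenset[str] | set[str]" = DEFAULT_LOF_CATEGORIES,
) -> VariantTable:
    """Restrict a variant table to its LOF sites.

    Category matching is case-insensitive; each distinct non-qualifying
    category is logged once.
    """
    cats = {c.lower() for c in categories}
    keep = []
    dropped: set[str] = set()
    for i, site in enumerate(vt.sites):
        if site.category.lower() in cats:
            keep.append(i)
        else:
            if site.category not in dropped:
                logger.info("category %r not in LOF set; sites dropped", site.category)
                dropped.add(site.category)
    return vt.subset_sites(keep)


def coseg_scan(
    lof: VariantTable,
    target_dosage: "Mapping[str, int] | Sequence[int]",
    target_hap: str = "target",
) -> list[CosegHit]:
    """Sites whose alt-dosage vector equals the target-haplotype copy numbers.

    ``target_dosage`` gives the target haplotype's copy number (0/1/2) per
    sequenced sample, either as a mapping keyed by sample_id (which must
    cover exactly the table's samples) or as a sequence parallel to the
    table's sample order.  The match is exact over all samples; a site
    matching all but one sample is not returned.
    """
    if isinstance(target_dosage, Mapping):
        if set(target_dosage) != set(lof.sample_ids):
            raise ValueError("sample sets of variant table and target dosages disagree")
        target = np.array([target_dosage[s] for s in lof.sample_ids], dtype=np.int8)
    else:
        if len(target_dosage) != lof.n_samples:
            raise ValueError("target dosage length does not match sample count")
        target = np.asarray(target_dosage, dtype=np.int8)
    hits = []
    for i, site in enumerate(lof.sites):
        if np.array_equal(lof.dosage[i, :], target):
            hits.append(CosegHit(site_id=site.site_id, gene=site.gene, target_hap=target_hap))
    return hits


def gene_burden_scan(
    lof: VariantTable,
    min_sites: int = 2,
    haldane: bool = False,
    bonferroni: bool = False,
) -> list[GeneBurdenRow]:
    """Gene-level LOF burden test; rows sorted by p (untested rows last).

    Allele conservation (alt + ref = 2 x n_cohort x n_sites per cohort)
    holds by construction and is asserted on every run.  ``haldane`` adds
    0.5 to every cell before testing when any cell is zero.
    """
    is_case = np.array([c == "case" for c in lof.cohorts])
    n_case = int(is_case.sum())
    n_ctrl = len(lof.cohorts) - n_case
    genes: dict[str, list[int]] = {}
    for i, site in enumerate(lof.sites):
        genes.setdefault(site.gene, []).append(i)

    rows: list[GeneBurdenRow] = []
    for gene, idx in genes.items():
        n_sites = len(idx)
        sub = lof.dosage[idx, :]
        alt_case = int(sub[:, is_case].sum())
        alt_ctrl = int(sub[:, ~is_case].sum())
        ref_case = 2 * n_case * n_sites - alt_case
        ref_ctrl = 2 * n_ctrl * n_sites - alt_ctrl
        assert alt_case + ref_case == 2 * n_case * n_sites
        assert alt_ctrl + ref_ctrl == 2 * n_ctrl * n_sites
        if n_sites < min_sites:
            result = None
        else:
            a, b, c, d = alt_case, ref_case, alt_ctrl, ref_ctrl
            if haldane and min(a, b, c, d) == 0:
                result = assoc_2x2(a + 0.5, b + 0.5, c + 0.5, d + 0.5)
            else:
                result = assoc_2x2(a, b, c, d)
        rows.append(
            GeneBurdenRow(
                gene=gene,
                n_lof_sites=n_sites,
                alt_case=alt_case,
                ref_case=ref_case,
                alt_control=alt_ctrl,
                ref_control=ref_ctrl,
                result=result,
            )
        )
    if bonferroni:
        m = sum(
            1 for r in rows if r.result is not None and not math.isnan(r.result.p)
        )
        adj = []
        for r in rows:
            if r.result is not None and not math.isnan(r.result.p):
                res = r.result
                res = Assoc2x2Result(
                    res.a, res.b, res.c, res.d, res.chi2, min(1.0, res.p * m),
                    res.or_, res.ci_low, res.ci_high, res.maf_case, res.maf_control,
                )
                r = GeneBurdenRow(
                    r.gene, r.n_lof_sites, r.alt_case, r.ref_case,
                    r.alt_control, r.ref_control, res,
                )
            adj.append(r)
        rows = adj

    def sort_key(r: GeneBurdenRow):
        if r.result is None or math.isnan(r.result.p):
            return (1, 0.0, r.gene)
        return (0, r.result.p, r.gene)

    rows.sort(key=sort_key)
    return rows


def burden_to_dataframe(rows: "list[GeneBurdenRow]") -> pd.DataFrame:
    na = float("nan")
    return pd.DataFrame(
        {
            "gene": [r.gene for r in rows],
            "n_lof_sites": [r.n_lof_sites for r in rows],
            "alt_case": [r.alt_case for r in rows],
            "ref_case": [r.ref_case for r in rows],
            "alt_control": [r.alt_control for r in rows],
            "ref_control": [r.ref_control for r in rows],
            "chi2": [r.result.chi2 if r.result else na for r in rows],
            "p": [r.result.p if r.result else na for r in rows],
            "OR": [r.result.or_ if r.result else na for r in rows],
            "ci_low": [r.result.ci_low if r.result else na for r in rows],
            "ci_high": [r.result.ci_high if r.result else na for r in rows],
        }
    )
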