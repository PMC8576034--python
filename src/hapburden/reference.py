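"""Published summary statistics for the 5q22.1 atopic-dermatitis locus.

These constants carry the study-level summary data the pipeline emulates
and recomputes: the marker panel of the haplotype block (four SNPs and six
deletions in strong LD), the seven common haplotypes (pooled frequency
above 0.5%) with their cohort frequencies, the headline cohort sizes, and
the per-gene loss-of-function allele-observation counts from the targeted
sequencing of 16 samples (8 cases, 8 controls).

Deletion alleles are written as ``-``.  The published table typography
(strikethrough for deleted bases) does not define a plain-text encoding, so
the deletion-bearing allele strings here are this package's own convention;
haplotype labels follow the published numbering for readability, but all
internal cross-referencing is by allele string.
"""

from __future__ import annotations

from hapburden.io_formats import Marker, MarkerPanel

#: Cohort sizes of the discovery (genotyping) stage.
N_CASE: int = 3624
N_CONTROL: int = 5076

#: Number of samples selected for targeted sequencing, per cohort.
N_SEQ_PER_COHORT: int = 8

#: The 10-marker haplotype block at 5q22.1 (chr5 positions are approximate
#: placements inside the ~2.9 Mb capture target; analyses depend only on
#: order and allele coding).
DEFAULT_PANEL = MarkerPanel(
    markers=(
        Marker("rs5870408", "G", "-", True, 110001000),
        Marker("rs140764268", "C", "-", True, 110002500),
        Marker("rs11357450", "C", "-", True, 110004000),
        Marker("rs35639206", "T", "-", True, 110006000),
        Marker("rs10067777", "A", "G", False, 110008000),
        Marker("rs7701890", "A", "G", False, 110010000),
        Marker("rs137936676", "C", "-", True, 110012000),
        Marker("rs13360927", "A", "G", False, 110014000),
        Marker("rs13361382", "G", "A", False, 110016000),
        Marker("rs10617471", "T", "-", True, 110018000),
    )
)

#: The seven common haplotypes (> 0.5% pooled frequency):
#: label -> (allele string, case %, control %).
COMMON_HAPLOTYPES: dict[str, tuple[str, float, float]] = {
    "H14": ("GCCTGGCGAT", 6.80, 5.52),
    "H15": ("----GA-AG-", 0.16, 0.94),
    "H43": ("----AA-AGT", 5.39, 4.63),
    "H47": ("----AG-GAT", 0.09, 0.57),
    "H54": ("GCCTGGCGA-", 0.55, 0.56),
    "H56": ("----GG-GAT", 4.12, 3.72),
    "H62": ("----AA-AG-", 23.19, 24.15),
}

#: Headline haplotype cohort frequencies (proportions) used for the
#: frequency-parameterised odds ratios.
HEADLINE_HAP_FREQS: dict[str, tuple[float, float]] = {
    label: (case_pct / 100.0, ctrl_pct / 100.0)
    for label, (_, case_pct, ctrl_pct) in COMMON_HAPLOTYPES.items()
}

#: Gene-level LOF allele observations from the targeted sequencing:
#: gene -> (alt_case, ref_case, alt_control, ref_control).  Each cohort
#: total equals 2 alleles x 8 samples x n LOF sites.
GENE_LOF_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "TMEM232": (20, 172, 50, 142),
    "CAMK4": (23, 73, 24, 72),
    "EPB41L4A": (155, 149, 157, 147),
    "LOC102467214": (47, 49, 46, 50),
    "MAN2A1": (118, 90, 118, 90),
    "SLC25A46": (34, 142, 45, 131),
    "NREP": (6, 106, 5, 107),
    "STARD4": (4, 28, 7, 25),
    "TSLP": (24, 120, 20, 124),
    "WDR36": (64, 272, 67, 269),
    "LOC100289673": (0, 32, 2, 30),
}


def gene_n_sites(gene: str) -> int:
    """Number of LOF sites per gene implied by the allele-count structure."""
    a, b, _, _ = GENE_LOF_COUNTS[gene]
    total = a + b
    n_sites, rem = divmod(total, 2 * N_SEQ_PER_COHORT)
    if rem:
        raise ValueError(f"{gene}: allele total {total} is not a multiple of 16")
    return n_sites
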