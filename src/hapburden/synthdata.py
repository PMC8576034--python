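"""Synthetic cohorts and sequencing fixtures with known ground truth.

The generator produces exactly the statistical structure the analysis
assumes, so every downstream stage can be validated offline:

* diplotypes are drawn i.i.d. from cohort-specific haplotype frequency
  distributions (cohort-wise random mating — the implicit model of the
  frequency-based 2x2 tests; no recombination, since the panel is one
  haplotype block in strong LD);
* per-gene LOF alt dosages are Binomial(2, alt_freq) per sample and site,
  independent of the diplotype (the null fixture), except for an optional
  planted site whose dosage tracks a target haplotype's copy number
  exactly — the positive control for the co-segregation scan;
* reads are constructed to lie strictly beyond or strictly within the
  read-filter thresholds, with labelled ground truth of which rule each
  violating read breaks.

One master seed drives per-stage derived streams; identical configuration
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from hapburden.io_formats import (
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    Read,
    ReadSet,
    VariantSite,
    VariantTable,
)
from hapburden.reference import (
    COMMON_HAPLOTYPES,
    DEFAULT_PANEL,
    GENE_LOF_COUNTS,
    N_SEQ_PER_COHORT,
    gene_n_sites,
)

_FREQ_TOL = 1e-9

# sub-stream indices under the master seed
_STREAM_GENOTYPES = 0
_STREAM_LOF = 1
_STREAM_READS = 2


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class LofSiteSpec:
    """One simulated LOF site: cohort alt-allele frequencies + annotation."""

    site_id: str
    alt_freq_case: float
    alt_freq_control: float
    category: str


@dataclass
class SimConfig:
    """Full configuration of a synthetic study.

    ``hap_freqs_*`` map haplotype allele strings to frequencies (each map
    must sum to 1); ``lof_spec`` maps gene symbol to its list of
    :class:`LofSiteSpec`.  ``coseg_target`` optionally plants one extra LOF
    site in ``coseg_gene`` whose dosage equals each individual's copy number
    of that haplotype.
    """

    panel: MarkerPanel
    hap_freqs_case: dict[str, float]
    hap_freqs_control: dict[str, float]
    n_case: int
    n_control: int
    lof_spec: dict[str, list[LofSiteSpec]] = field(default_factory=dict)
    coseg_target: str | None = None
    coseg_gene: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ConfigError("n_case and n_control must be >= 1")
        for name, freqs in (
            ("hap_freqs_case", self.hap_freqs_case),
            ("hap_freqs_control", self.hap_freqs_control),
        ):
            if not freqs:
                raise ConfigError(f"{name} is empty")
            if any(f < 0 for f in freqs.values()):
                raise ConfigError(f"{name}: negative frequency")
            total = sum(freqs.values())
            if abs(total - 1.0) > _FREQ_TOL:
                raise ConfigError(f"{name}: frequencies sum to {total}, not 1")
            for hap in freqs:
                self.panel.alt_mask(hap)  # raises on invalid allele string
        for gene, sites in self.lof_spec.items():
            for s in sites:
                if not (0.0 <= s.alt_freq_case <= 1.0 and 0.0 <= s.alt_freq_control <= 1.0):
                    raise ConfigError(f"{gene}/{s.site_id}: alt frequency outside [0, 1]")
        if self.coseg_target is not None:
            try:
                self.panel.alt_mask(self.coseg_target)
            except ValueError as exc:
                raise ConfigError(
                    f"coseg_target {self.coseg_target!r} is not a haplotype of the panel"
                ) from exc
            if self.coseg_gene is not None and self.coseg_gene not in self.lof_spec:
                raise ConfigError(f"coseg_gene {self.coseg_gene!r} not in lof_spec")

    # -- serialisation ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "panel": [asdict(m) for m in self.panel.markers],
            "hap_freqs_case": dict(self.hap_freqs_case),
            "hap_freqs_control": dict(self.hap_freqs_control),
            "n_case": self.n_case,
            "n_control": self.n_control,
            "lof_spec": {
                gene: [asdict(s) for s in sites]
                for gene, sites in self.lof_spec.items()
            },
            "coseg_target": self.coseg_target,
            "coseg_gene": self.coseg_gene,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text())
        panel = MarkerPanel(markers=tuple(Marker(**m) for m in doc["panel"]))
        lof_spec = {
            gene: [LofSiteSpec(**s) for s in sites]
            for gene, sites in (doc.get("lof_spec") or {}).items()
        }
        return cls(
            panel=panel,
            hap_freqs_case={k: float(v) for k, v in doc["hap_freqs_case"].items()},
            hap_freqs_control={k: float(v) for k, v in doc["hap_freqs_control"].items()},
            n_case=int(doc["n_case"]),
            n_control=int(doc["n_control"]),
            lof_spec=lof_spec,
            coseg_target=doc.get("coseg_target"),
            coseg_gene=doc.get("coseg_gene"),
            seed=int(doc.get("seed", 0)),
        )


def default_sim_config(
    n_case: int = 500,
    n_control: int = 500,
    seed: int = 0,
    coseg_target: str | None = None,
) -> SimConfig:
    """Study-shaped default configuration.

    Haplotype frequencies are the seven published common haplotypes of the
    5q22.1 block with each cohort's frequencies renormalised to sum to 1
    (the published vector covers only the common haplotypes); the LOF
    specification mirrors the published per-gene count structure, with each
    gene's number of sites recovered from its allele totals and per-site
    alt frequencies equal to the gene-level published cohort rates.
    """
    case = {s: f for (s, f, _) in COMMON_HAPLOTYPES.values()}
    ctrl = {s: f for (s, _, f) in COMMON_HAPLOTYPES.values()}
    case_total = sum(case.values())
    ctrl_total = sum(ctrl.values())
    hap_freqs_case = {h: f / case_total for h, f in case.items()}
    hap_freqs_control = {h: f / ctrl_total for h, f in ctrl.items()}
    lof_spec: dict[str, list[LofSiteSpec]] = {}
    for gene, (a, b, c, d) in GENE_LOF_COUNTS.items():
        n_sites = gene_n_sites(gene)
        f_case = a / (a + b)
        f_ctrl = c / (c + d)
        lof_spec[gene] = [
            LofSiteSpec(
                site_id=f"{gene}_s{k + 1}",
                alt_freq_case=f_case,
                alt_freq_control=f_ctrl,
                category="exonic",
            )
            for k in range(n_sites)
        ]
    return SimConfig(
        panel=DEFAULT_PANEL,
        hap_freqs_case=hap_freqs_case,
        hap_freqs_control=hap_freqs_control,
        n_case=n_case,
        n_control=n_control,
        lof_spec=lof_spec,
        coseg_target=coseg_target,
        coseg_gene=next(iter(lof_spec)) if coseg_target else None,
        seed=seed,
    )


def _stage_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def simulate_cohort_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Draw case/control diplotypes and return unphased genotypes + truth.

    Each individual's two haplotypes are drawn i.i.d. from its cohort's
    frequency map (random mating within cohort).  The returned truth list
    holds the ordered haplotype-string pair per individual, parallel to the
    genotype matrix's sample order (cases first).
    """
    rng = _stage_rng(cfg.seed, _STREAM_GENOTYPES)
    masks = {}
    for hap in set(cfg.hap_freqs_case) | set(cfg.hap_freqs_control):
        masks[hap] = np.array(cfg.panel.alt_mask(hap), dtype=np.int8)

    sample_ids: list[str] = []
    cohorts: list[str] = []
    truth: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    for cohort, n, freqs in (
        ("case", cfg.n_case, cfg.hap_freqs_case),
        ("control", cfg.n_control, cfg.hap_freqs_control),
    ):
        haps = sorted(freqs)
        probs = np.array([freqs[h] for h in haps], dtype=float)
        probs /= probs.sum()
        draws = rng.choice(len(haps), size=(n, 2), p=probs)
        for i in range(n):
            h1, h2 = haps[draws[i, 0]], haps[draws[i, 1]]
            truth.append((h1, h2))
            rows.append(masks[h1] + masks[h2])
            sample_ids.append(f"{cohort}_{i + 1:05d}")
            cohorts.append(cohort)
    gm = GenotypeMatrix(
        panel=cfg.panel,
        sample_ids=sample_ids,
        cohorts=cohorts,
        dosage=np.vstack(rows).astype(np.int8),
    )
    return gm, truth


def simulate_lof_variants(
    cfg: SimConfig,
    samples: list[tuple[str, str]],
    truth: list[tuple[str, str]],
) -> VariantTable:
    """Draw per-sample LOF alt dosages for every configured gene.

    Dosages are Binomial(2, alt_freq) with the cohort's per-site frequency,
    independent across samples and sites (and of the diplotype).  If
    ``cfg.coseg_target`` is set, one extra site is appended to
    ``cfg.coseg_gene`` (default: the first gene of ``lof_spec``) whose
    dosage equals each individual's copy number of the target haplotype —
    a perfectly co-segregating variant.

    Per cohort and gene the alt+ref observation total is
    2 x n_cohort x n_sites(gene) by construction.
    """
    if not cfg.lof_spec:
        raise ConfigError("lof_spec is empty")
    if len(samples) != len(truth):
        raise ValueError("samples and truth must be parallel")
    rng = _stage_rng(cfg.seed, _STREAM_LOF)
    sample_ids = [s for s, _ in samples]
    cohorts = [c for _, c in samples]
    is_case = np.array([c == "case" for c in cohorts])

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for g_idx, (gene, specs) in enumerate(cfg.lof_spec.items()):
        base_pos = 109_100_000 + g_idx * 150_000
        for s_idx, spec in enumerate(specs):
            p = np.where(is_case, spec.alt_freq_case, spec.alt_freq_control)
            dose = rng.binomial(2, p).astype(np.int8)
            sites.append(
                VariantSite(
                    site_id=spec.site_id,
                    gene=gene,
                    position=base_pos + s_idx * 500,
                    category=spec.category,
                )
            )
            rows.append(dose)
        if cfg.coseg_target is not None and gene == (
            cfg.coseg_gene or next(iter(cfg.lof_spec))
        ):
            copies = np.array(
                [
                    (h1 == cfg.coseg_target) + (h2 == cfg.coseg_target)
                    for h1, h2 in truth
                ],
                dtype=np.int8,
            )
            sites.append(
                VariantSite(
                    site_id=f"{gene}_coseg",
                    gene=gene,
                    position=base_pos + len(specs) * 500,
                    category="splicing",
                )
            )
            rows.append(copies)
    return VariantTable(
        sites=sites,
        sample_ids=sample_ids,
        cohorts=cohorts,
        dosage=np.vstack(rows).astype(np.int8),
    )


_BASES = np.array(list("ACGT"))


def _random_bases(rng: np.random.Generator, length: int, forbid: str | None) -> str:
    """Random sequence of *length* that does not contain *forbid*."""
    while True:
        s = "".join(rng.choice(_BASES, size=length))
        if not forbid or forbid not in s:
            return s


def simulate_reads(
    n_reads: int,
    read_len: int,
    adapter: str,
    frac_adapter: float = 0.0,
    frac_lowq: float = 0.0,
    frac_highN: float = 0.0,
    seed: int = 0,
) -> tuple[ReadSet, dict[str, str | None]]:
    """Construct reads straddling the three read-filter rules.

    Exactly ``round(frac * n_reads)`` reads are built to violate each rule,
    strictly beyond its threshold (adapter present as a substring; > 50% of
    bases at Phred <= 5; > 10% ``N``); the remaining reads are strictly
    within every threshold.  Returns the shuffled read set and a ground
    truth map ``read_id -> rule`` (``"adapter"``, ``"low_quality"``,
    ``"high_N"``) or ``None`` for clean reads.
    """
    for name, frac in (
        ("frac_adapter", frac_adapter),
        ("frac_lowq", frac_lowq),
        ("frac_highN", frac_highN),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if frac_adapter + frac_lowq + frac_highN > 1.0 + 1e-12:
        raise ValueError("violation fractions must sum to at most 1")
    if frac_adapter > 0 and read_len < len(adapter):
        raise ValueError("read_len is shorter than the adapter sequence")

    rng = _stage_rng(seed, _STREAM_READS)
    n_adapter = round(frac_adapter * n_reads)
    n_lowq = round(frac_lowq * n_reads)
    n_highN = round(frac_highN * n_reads)
    labels = (
        ["adapter"] * n_adapter
        + ["low_quality"] * n_lowq
        + ["high_N"] * n_highN
        + [None] * (n_reads - n_adapter - n_lowq - n_highN)
    )
    order = rng.permutation(n_reads)

    reads: list[Read] = []
    truth: dict[str, str | None] = {}
    for k in range(n_reads):
        label = labels[order[k]]
        read_id = f"read_{k + 1:06d}"
        quals = list(rng.integers(30, 41, size=read_len))
        if label == "adapter":
            bases = _random_bases(rng, read_len, None)
            off = int(rng.integers(0, read_len - len(adapter) + 1))
            bases = bases[:off] + adapter + bases[off + len(adapter):]
        elif label == "low_quality":
            bases = _random_bases(rng, read_len, adapter or None)
            k_low = read_len // 2 + 1  # strictly more than 50%
            pos = rng.choice(read_len, size=k_low, replace=False)
            for p_ in pos:
                quals[p_] = int(rng.integers(0, 6))
        elif label == "high_N":
            k_n = read_len // 10 + 1  # strictly more than 10%
            while True:
                bases = _random_bases(rng, read_len, None)
                pos = rng.choice(read_len, size=k_n, replace=False)
                arr = np.array(list(bases))
                arr[pos] = "N"
                bases = "".join(arr)
                if not adapter or adapter not in bases:
                    break
        else:
            bases = _random_bases(rng, read_len, adapter or None)
        reads.append(Read(read_id=read_id, bases=bases, quals=quals))
        truth[read_id] = label
    return ReadSet(reads=reads), truth
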