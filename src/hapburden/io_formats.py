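"""Readers, writers and in-memory containers for the pipeline's formats.

Every other module consumes and produces the types defined here:

* :class:`MarkerPanel` — the ordered biallelic markers of the haplotype block
  (SNPs and deletions; deletion alleles are written as ``-``).
* :class:`GenotypeMatrix` — unphased per-individual genotypes with
  case/control labels.  Because the panel is biallelic, a genotype is stored
  as the alternative-allele dosage (0/1/2, :data:`MISSING` = -1).
* :class:`ReadSet` — raw reads for the QC stage (FASTQ, Phred+33).
* :class:`VariantTable` — per-sample alt dosages at sequenced sites together
  with gene symbol and functional annotation category.
* :class:`Region` — a BED-style half-open interval.

Coordinate conventions: VCF positions are 1-based, BED intervals half-open
0-based.  Multi-allelic VCF records are rejected — the panel and the
sequenced sites handled here are biallelic throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in :class:`GenotypeMatrix`.
MISSING: int = -1


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    """One biallelic variant of the panel."""

    id: str
    ref_allele: str
    alt_allele: str
    is_indel: bool
    position: int  # 1-based on the chromosome

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered panel of biallelic markers forming one haplotype block."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 1:
            raise ValueError("panel must contain at least one marker")
        ids = [m.id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        positions = [m.position for m in self.markers]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("marker positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def haplotype_string(self, alt_mask: Sequence[int]) -> str:
        """Allele string for a haplotype given per-marker alt indicators."""
        if len(alt_mask) != len(self.markers):
            raise ValueError("alt_mask length does not match panel size")
        return "".join(
            m.alt_allele if alt else m.ref_allele
            for m, alt in zip(self.markers, alt_mask)
        )

    def alt_mask(self, allele_string: str) -> tuple[int, ...]:
        """Inverse of :meth:`haplotype_string`; raises if an allele is unknown."""
        if len(allele_string) != len(self.markers):
            raise ValueError("allele string length does not match panel size")
        mask = []
        for m, a in zip(self.markers, allele_string):
            if a == m.ref_allele:
                mask.append(0)
            elif a == m.alt_allele:
                mask.append(1)
            else:
                raise ValueError(
                    f"allele {a!r} is neither ref nor alt of marker {m.id}"
                )
        return tuple(mask)


@dataclass
class GenotypeMatrix:
    """Unphased genotypes for a case/control cohort over a marker panel.

    ``dosage[i, j]`` holds individual *i*'s alternative-allele count at
    marker *j* (0, 1, 2) or :data:`MISSING`.  An unordered allele pair is
    equivalent to this encoding because every marker is biallelic.
    """

    panel: MarkerPanel
    sample_ids: list[str]
    cohorts: list[str]  # "case" or "control", parallel to sample_ids
    dosage: np.ndarray  # shape (n_individuals, n_markers), int8

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or n != len(self.cohorts):
            raise ValueError("sample_ids/cohorts length does not match dosage rows")
        if m != len(self.panel):
            raise ValueError("dosage columns do not match panel size")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        bad = set(self.cohorts) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")
        valid = np.isin(self.dosage, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosage entries must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_case(self) -> int:
        return sum(c == "case" for c in self.cohorts)

    @property
    def n_control(self) -> int:
        return sum(c == "control" for c in self.cohorts)

    def has_missing(self) -> np.ndarray:
        """Boolean mask of individuals with at least one missing genotype."""
        return (self.dosage == MISSING).any(axis=1)


@dataclass
class Read:
    """A single sequencing read (bases over {A,C,G,T,N}, Phred qualities)."""

    read_id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.read_id}: bases/quals length mismatch")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.read_id}: negative quality score")


@dataclass
class ReadSet:
    """An ordered collection of reads."""

    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    @property
    def n_bases(self) -> int:
        return sum(len(r.bases) for r in self.reads)


@dataclass(frozen=True)
class VariantSite:
    """One sequenced biallelic site with its functional annotation."""

    site_id: str
    gene: str
    position: int  # 1-based
    category: str  # ANNOVAR-style functional category

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"site {self.site_id}: empty gene symbol")
        if not self.category:
            raise ValueError(f"site {self.site_id}: empty annotation category")


@dataclass
class VariantTable:
    """Per-sample alt-allele dosages at annotated sequenced sites."""

    sites: list[VariantSite]
    sample_ids: list[str]
    cohorts: list[str]
    dosage: np.ndarray  # shape (n_sites, n_samples), int8, values 0/1/2

    def __post_init__(self) -> None:
        s, n = self.dosage.shape
        if s != len(self.sites):
            raise ValueError("dosage rows do not match number of sites")
        if n != len(self.sample_ids) or n != len(self.cohorts):
            raise ValueError("dosage columns do not match sample list")
        if not np.isin(self.dosage, (0, 1, 2)).all():
            raise ValueError("dosage entries must be in {0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_sites(self, keep: Sequence[int]) -> "VariantTable":
        keep = list(keep)
        return VariantTable(
            sites=[self.sites[i] for i in keep],
            sample_ids=list(self.sample_ids),
            cohorts=list(self.cohorts),
            dosage=self.dosage[keep, :].copy(),
        )


@dataclass(frozen=True)
class Region:
    """Half-open genomic interval (BED convention: 0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.chrom}:{self.start}-{self.end}: start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------

_MISSING_GT = "./."


def read_genotype_table(path: str | Path, panel: MarkerPanel) -> GenotypeMatrix:
    """Read an unphased genotype TSV into a :class:`GenotypeMatrix`.

    Expected layout: a header line ``sample_id<TAB>cohort<TAB><marker ids...>``
    followed by one row per individual whose marker columns hold an unordered
    allele pair ``A1/A2`` or the missing sentinel ``./.``.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "cohort"] + panel.ids
        if header != expected:
            raise FormatError(
                f"{path}: header {header!r} does not match expected {expected!r}"
            )
        sample_ids: list[str] = []
        cohorts: list[str] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(expected):
                raise FormatError(f"{path}:{lineno}: expected {len(expected)} columns")
            sid, cohort = fields[0], fields[1]
            if sid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            row = []
            for marker, cell in zip(panel.markers, fields[2:]):
                row.append(_parse_genotype_cell(cell, marker, path, lineno))
            sample_ids.append(sid)
            cohorts.append(cohort)
            rows.append(row)
    dosage = np.array(rows, dtype=np.int8).reshape(len(rows), len(panel))
    return GenotypeMatrix(panel=panel, sample_ids=sample_ids, cohorts=cohorts, dosage=dosage)


def _parse_genotype_cell(cell: str, marker: Marker, path: Path, lineno: int) -> int:
    if cell == _MISSING_GT:
        return MISSING
    parts = cell.split("/")
    if len(parts) != 2:
        raise FormatError(
            f"{path}:{lineno}: column {marker.id}: malformed genotype {cell!r}"
        )
    dose = 0
    for allele in parts:
        if allele == marker.alt_allele:
            dose += 1
        elif allele != marker.ref_allele:
            raise FormatError(
                f"{path}:{lineno}: column {marker.id}: allele {allele!r} is not "
                f"one of {{{marker.ref_allele!r}, {marker.alt_allele!r}}}"
            )
    return dose


def write_genotype_table(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a :class:`GenotypeMatrix` in the TSV dialect of
    :func:`read_genotype_table`; the round trip is the identity."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["sample_id", "cohort"] + gm.panel.ids) + "\n")
        for i, (sid, cohort) in enumerate(zip(gm.sample_ids, gm.cohorts)):
            cells = []
            for j, m in enumerate(gm.panel.markers):
                d = int(gm.dosage[i, j])
                if d == MISSING:
                    cells.append(_MISSING_GT)
                else:
                    alleles = [m.ref_allele] * (2 - d) + [m.alt_allele] * d
                    cells.append("/".join(alleles))
            fh.write("\t".join([sid, cohort] + cells) + "\n")


# ---------------------------------------------------------------------------
# VCF + annotation TSV -> VariantTable
# ---------------------------------------------------------------------------


def read_variant_table(
    vcf_path: str | Path,
    annotation_path: str | Path,
    cohorts: str | Path | Mapping[str, str],
) -> VariantTable:
    """Build a :class:`VariantTable` from a VCF and an annotation TSV.

    Parameters
    ----------
    vcf_path
        VCF v4.x with GT fields for every sample.  Only the GT subfield is
        used; multi-allelic records are rejected.
    annotation_path
        TSV with header ``site_id<TAB>gene<TAB>category``.  Sites present in
        the VCF but absent here are dropped with a logged warning.
    cohorts
        Mapping ``sample_id -> cohort`` or path to a two-column TSV
        (``sample_id<TAB>cohort``, with header).  Its sample set must match
        the VCF's exactly.
    """
    from cyvcf2 import VCF

    if not isinstance(cohorts, Mapping):
        cohorts = read_cohort_table(cohorts)

    annotations = _read_annotation_tsv(annotation_path)

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if set(samples) != set(cohorts):
        raise FormatError(
            "sample sets of VCF and cohort-label table disagree: "
            f"VCF-only={sorted(set(samples) - set(cohorts))}, "
            f"labels-only={sorted(set(cohorts) - set(samples))}"
        )

    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{vcf_path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                "is not supported"
            )
        site_id = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if site_id not in annotations:
            logger.warning("site %s has no annotation row; dropped", site_id)
            n_dropped += 1
            continue
        gene, category = annotations[site_id]
        # rec.genotypes: [allele1, allele2, phased] per sample
        dose = np.array(
            [g[0] + g[1] for g in rec.genotypes], dtype=np.int8
        )
        sites.append(
            VariantSite(site_id=site_id, gene=gene, position=rec.POS, category=category)
        )
        rows.append(dose)
    vcf.close()
    if n_dropped:
        logger.warning("%d unannotated site(s) dropped from %s", n_dropped, vcf_path)

    dosage = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    return VariantTable(
        sites=sites,
        sample_ids=samples,
        cohorts=[cohorts[s] for s in samples],
        dosage=dosage,
    )


def _read_annotation_tsv(path: str | Path) -> dict[str, tuple[str, str]]:
    path = Path(path)
    out: dict[str, tuple[str, str]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["site_id", "gene", "category"]:
            raise FormatError(
                f"{path}: annotation header must start with site_id, gene, category"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 columns")
            out[fields[0]] = (fields[1], fields[2])
    return out


def read_cohort_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>cohort`` TSV (with header)."""
    path = Path(path)
    out: dict[str, str] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "cohort"]:
            raise FormatError(f"{path}: cohort header must be sample_id, cohort")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if fields[0] in out:
                raise FormatError(f"{path}:{lineno}: duplicate sample_id {fields[0]!r}")
            out[fields[0]] = fields[1]
    return out


def write_vcf(vt: VariantTable, path: str | Path, chrom: str = "chr5") -> None:
    """Write a minimal VCF v4.2 (GT only) for a :class:`VariantTable`."""
    path = Path(path)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.sample_ids)
            + "\n"
        )
        for i, site in enumerate(vt.sites):
            gts = "\t".join(gt_strings[int(d)] for d in vt.dosage[i, :])
            fh.write(
                f"{chrom}\t{site.position}\t{site.site_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_annotation_table(vt: VariantTable, path: str | Path) -> None:
    """Write the ``site_id / gene / category`` annotation TSV for *vt*."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("site_id\tgene\tcategory\n")
        for site in vt.sites:
            fh.write(f"{site.site_id}\t{site.gene}\t{site.category}\n")


def write_cohort_table(sample_ids: Sequence[str], cohorts: Sequence[str], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tcohort\n")
        for sid, cohort in zip(sample_ids, cohorts):
            fh.write(f"{sid}\t{cohort}\n")


# ---------------------------------------------------------------------------
# Marker panel TSV
# ---------------------------------------------------------------------------


def read_panel(path: str | Path) -> MarkerPanel:
    """Read a marker panel TSV (id, ref_allele, alt_allele, is_indel, position)."""
    path = Path(path)
    markers = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["id", "ref_allele", "alt_allele", "is_indel", "position"]
        if header != expected:
            raise FormatError(f"{path}: panel header must be {expected}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            markers.append(
                Marker(
                    id=fields[0],
                    ref_allele=fields[1],
                    alt_allele=fields[2],
                    is_indel=fields[3].lower() in ("1", "true", "yes"),
                    position=int(fields[4]),
                )
            )
    return MarkerPanel(markers=tuple(markers))


def write_panel(panel: MarkerPanel, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tref_allele\talt_allele\tis_indel\tposition\n")
        for m in panel.markers:
            fh.write(
                f"{m.id}\t{m.ref_allele}\t{m.alt_allele}\t"
                f"{'true' if m.is_indel else 'false'}\t{m.position}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path) -> ReadSet:
    """Read a Phred+33 FASTQ file into a :class:`ReadSet`.

    A truncated trailing record raises :class:`FormatError` naming the record
    index.
    """
    path = Path(path)
    reads: list[Read] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                Read(
                    read_id=rec.id,
                    bases=str(rec.seq),
                    quals=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise FormatError(
            f"{path}: malformed FASTQ near record {len(reads) + 1}: {exc}"
        ) from exc
    return ReadSet(reads=reads)


def write_fastq(rs: ReadSet, path: str | Path) -> None:
    """Write a :class:`ReadSet` as Phred+33 FASTQ; read∘write is the identity."""
    path = Path(path)
    records = []
    for r in rs.reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = r.quals
        records.append(rec)
    with path.open("w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> list[Region]:
    """Read a BED3 file into a list of :class:`Region`."""
    path = Path(path)
    regions = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected ≥3 BED columns")
            regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
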