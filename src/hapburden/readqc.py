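"""Read-level QC: the three-rule "clean data" filter and summary stats.

A read is removed iff it (1) contains the sequencing adapter as a
substring, or (2) has strictly more than 50% of its bases at Phred quality
<= 5, or (3) has strictly more than 10% unknown (``N``) bases.  All
thresholds are strict inequalities; attribution of a removed read is to the
first violated rule in that order.  The adapter test is an exact substring
match by default (a maximum-mismatch option exists, defaulting to 0, since
no published matching algorithm is assumed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from hapburden.io_formats import ReadSet


@dataclass
class ReadQCReport:
    """Summary of one filtering pass."""

    n_raw: int = 0
    n_clean: int = 0
    raw_bases: int = 0
    clean_bases: int = 0
    gc_content: float = float("nan")  # of clean, non-N bases
    removed_by: dict[str, int] = field(
        default_factory=lambda: {"adapter": 0, "low_quality": 0, "high_N": 0}
    )

    def to_dict(self) -> dict:
        return {
            "n_raw": self.n_raw,
            "n_clean": self.n_clean,
            "raw_bases": self.raw_bases,
            "clean_bases": self.clean_bases,
            "gc_content": None if math.isnan(self.gc_content) else self.gc_content,
            "removed_by": dict(self.removed_by),
        }


def _contains_adapter(bases: str, adapter: str, max_mismatch: int) -> bool:
    if max_mismatch <= 0:
        return adapter in bases
    la = len(adapter)
    for off in range(len(bases) - la + 1):
        mism = 0
        for x, y in zip(bases[off : off + la], adapter):
            if x != y:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            return True
    return False


def violated_rule(
    bases: str,
    quals: list[int],
    adapter: str,
    lowq_threshold: int = 5,
    lowq_frac: float = 0.5,
    n_frac: float = 0.1,
    max_mismatch: int = 0,
) -> str | None:
    """First filter rule a read violates, or None if it is clean.

    ``N`` bases count toward the low-quality denominator with whatever
    quality the FASTQ assigns them.
    """
    if adapter and _contains_adapter(bases, adapter, max_mismatch):
        return "adapter"
    n = len(bases)
    if n:
        if sum(q <= lowq_threshold for q in quals) > lowq_frac * n:
            return "low_quality"
        if bases.count("N") > n_frac * n:
            return "high_N"
    return None


def filter_reads(
    rs: ReadSet,
    adapter: str,
    lowq_threshold: int = 5,
    lowq_frac: float = 0.5,
    n_frac: float = 0.1,
    max_mismatch: int = 0,
) -> tuple[ReadSet, ReadQCReport]:
    """Apply the three-rule filter; returns the clean reads and a report.

    Filtering is idempotent: running it on its own clean output removes
    nothing.
    """
    if not adapter:
        raise ValueError("adapter sequence must be nonempty")
    if not (0.0 <= lowq_frac <= 1.0 and 0.0 <= n_frac <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    clean = []
    report = ReadQCReport(n_raw=len(rs), raw_bases=rs.n_bases)
    for read in rs:
        rule = violated_rule(
            read.bases, read.quals, adapter, lowq_threshold, lowq_frac, n_frac, max_mismatch
        )
        if rule is None:
            clean.append(read)
        else:
            report.removed_by[rule] += 1
    clean_set = ReadSet(reads=clean)
    report.n_clean = len(clean_set)
    report.clean_bases = clean_set.n_bases
    report.gc_content = gc_content(clean_set) if clean_set.n_bases else float("nan")
    return clean_set, report


def gc_content(rs: ReadSet) -> float:
    """(G + C) / (A + C + G + T) over all reads; NaN if no non-N base."""
    gc = 0
    acgt = 0
    for read in rs:
        gc += read.bases.count("G") + read.bases.count("C")
        acgt += sum(read.bases.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return gc / acgt
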