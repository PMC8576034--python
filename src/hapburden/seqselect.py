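"""Haplotype-guided selection of samples for targeted sequencing.

Selection follows four rules applied greedily in strict order:

1. homozygotes for the top-associated (target) haplotype, as many as
   available;
2. heterozygous carriers of the target haplotype;
3. one carrier of each common haplotype (pooled frequency above the
   threshold, default 0.5%) not yet represented in a selected diplotype;
4. reference samples that do not carry the target haplotype (default 2).

Rules 1-2 reserve slots for the later rules: a carrier is only admitted if
enough capacity remains to cover every still-unrepresented common
haplotype that somebody in the cohort carries (one slot each, a
conservative bound since one diplotype can cover two) plus the outstanding
reference quota.  Non-carriers admitted by any rule count toward the
reference quota.  If slots remain after rule 4 they are backfilled with
the remaining target carriers, then anyone, so a sufficiently large cohort
yields exactly ``n_total`` samples.

Case/control balance is enforced by alternating picks between cohorts
within each rule; ties are broken by sample_id order, so the procedure is
fully deterministic.  An optional per-sample eligibility flag models
DNA-quality screening (all samples eligible by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from hapburden.phasing import DiplotypeAssignment, HaplotypeFreqTable, PhasedCohort

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    target_hap: str
    n_total: int
    common_freq_threshold: float = 0.005
    n_reference: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.common_freq_threshold < 1.0):
            raise ValueError("common_freq_threshold must lie in (0, 1)")
        if self.n_reference > self.n_total:
            raise ValueError("n_reference cannot exceed n_total")


@dataclass(frozen=True)
class SelectedSample:
    sample_id: str
    cohort: str
    diplotype: tuple[str, str]  # hap_id pair
    selection_reason: str  # homozygote | heterozygote | common:<hap> | reference | backfill


def _alternate(
    candidates: list[DiplotypeAssignment], start_cohort: str
) -> list[DiplotypeAssignment]:
    """Interleave case and control candidates, starting with *start_cohort*."""
    queues = {
        "case": [a for a in candidates if a.cohort == "case"],
        "control": [a for a in candidates if a.cohort == "control"],
    }
    out = []
    turn = start_cohort
    other = {"case": "control", "control": "case"}
    while queues["case"] or queues["control"]:
        if queues[turn]:
            out.append(queues[turn].pop(0))
        turn = other[turn]
        if not queues[turn]:
            turn = other[turn]
    return out


def select_sequencing_samples(
    pc: PhasedCohort,
    ft: HaplotypeFreqTable,
    cfg: SelectionConfig,
    eligible: Mapping[str, bool] | None = None,
) -> list[SelectedSample]:
    """Apply the four-rule selection to a phased cohort.

    Raises ``KeyError`` if the target haplotype is absent from the
    frequency table and ``ValueError`` if nobody carries it.  If
    ``n_total`` exceeds the cohort size, everyone (eligible) is selected
    with a logged warning.
    """
    ft.by_id(cfg.target_hap)  # KeyError if unknown
    pool = sorted(pc.assignments, key=lambda a: a.sample_id)
    if eligible is not None:
        pool = [a for a in pool if eligible.get(a.sample_id, True)]
    if cfg.n_total >= len(pool):
        logger.warning(
            "n_total=%d >= cohort size %d; selecting everyone", cfg.n_total, len(pool)
        )

    def copies(a: DiplotypeAssignment) -> int:
        return (a.hap1 == cfg.target_hap) + (a.hap2 == cfg.target_hap)

    if not any(copies(a) for a in pool):
        raise ValueError(f"no sample carries target haplotype {cfg.target_hap}")

    common = set(ft.common_ids(cfg.common_freq_threshold))
    # common haplotypes carried by anyone in the cohort (coverage universe)
    carried_common = {
        h for a in pool for h in (a.hap1, a.hap2) if h in common
    }

    selected: list[SelectedSample] = []
    chosen: set[str] = set()
    represented: set[str] = set()
    n_noncarrier = 0

    def admit(a: DiplotypeAssignment, reason: str) -> None:
        nonlocal n_noncarrier
        selected.append(
            SelectedSample(
                sample_id=a.sample_id,
                cohort=a.cohort,
                diplotype=(a.hap1, a.hap2),
                selection_reason=reason,
            )
        )
        chosen.add(a.sample_id)
        represented.update((a.hap1, a.hap2))
        if copies(a) == 0:
            n_noncarrier += 1

    def reserve_after(a: DiplotypeAssignment) -> int:
        """Slots that must stay free for rules 3-4 if *a* is admitted now."""
        rep = represented | {a.hap1, a.hap2}
        unrep = carried_common - rep
        ref_need = max(0, cfg.n_reference - n_noncarrier - (copies(a) == 0))
        return len(unrep) + ref_need

    # rules 1 and 2: target homozygotes, then heterozygotes
    for want, reason in ((2, "homozygote"), (1, "heterozygote")):
        for a in _alternate(
            [a for a in pool if copies(a) == want and a.sample_id not in chosen],
            "case",
        ):
            if len(selected) + 1 + reserve_after(a) > cfg.n_total:
                continue
            admit(a, reason)

    # rule 3: cover each not-yet-represented common haplotype
    order = sorted(
        carried_common, key=lambda h: (-ft.by_id(h).freq_pooled, h)
    )
    parity = "case"
    for hap in order:
        if hap in represented:
            continue
        carriers = [
            a for a in pool if a.sample_id not in chosen and hap in (a.hap1, a.hap2)
        ]
        if not carriers:
            continue
        ranked = _alternate(carriers, parity)
        for a in ranked:
            ref_need = max(0, cfg.n_reference - n_noncarrier - (copies(a) == 0))
            if len(selected) + 1 + ref_need <= cfg.n_total:
                admit(a, f"common:{hap}")
                parity = "control" if a.cohort == "case" else "case"
            break

    # rule 4: top up reference non-carriers
    for a in _alternate(
        [a for a in pool if a.sample_id not in chosen and copies(a) == 0], "case"
    ):
        if n_noncarrier >= cfg.n_reference or len(selected) >= cfg.n_total:
            break
        admit(a, "reference")

    # backfill any slack: remaining target carriers first (most copies
    # first), then anyone, keeping cohort alternation
    if len(selected) < cfg.n_total:
        rest = [a for a in pool if a.sample_id not in chosen]
        rest.sort(key=lambda a: (-copies(a), a.sample_id))
        for a in _alternate(rest, "case"):
            if len(selected) >= cfg.n_total:
                break
            admit(a, "backfill")

    return selected
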