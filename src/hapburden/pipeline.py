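"""End-to-end orchestration: simulate -> phase -> associate -> select ->
sequence QC -> LOF classification -> co-segregation -> burden.

The stage order mirrors the study design being emulated: haplotypes are
defined on the full cohorts, the top-associated haplotype guides the
selection of a small sequencing subset, and the sequencing-side analyses
(read QC, co-segregation scan, gene burden) run on that subset only.
Every stage reads and writes the pipeline's exchange formats, so each
intermediate is inspectable; a machine-readable ``summary.json`` collects
all result tables.  Identical configuration (including the master seed)
produces a byte-identical summary.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from hapburden import io_formats
from hapburden.hapassoc import (
    haplotype_assoc_scan,
    haplotypes_to_biallelic,
    scan_to_dataframe,
)
from hapburden.lofburden import (
    DEFAULT_LOF_CATEGORIES,
    burden_to_dataframe,
    classify_lof,
    coseg_scan,
    gene_burden_scan,
)
from hapburden.phasing import (
    PhasedCohort,
    em_estimate,
    write_freq_table,
    write_phased,
)
from hapburden.readqc import filter_reads
from hapburden.seqselect import SelectionConfig, select_sequencing_samples
from hapburden.synthdata import (
    SimConfig,
    default_sim_config,
    simulate_cohort_genotypes,
    simulate_lof_variants,
    simulate_reads,
)

logger = logging.getLogger(__name__)

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # standard short adapter prefix


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig
    out_dir: Path
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    n_select: int = 16
    n_reference: int = 2
    common_freq_threshold: float = 0.005
    adapter: str = DEFAULT_ADAPTER
    n_reads: int = 2000
    read_len: int = 100
    frac_adapter: float = 0.05
    frac_lowq: float = 0.05
    frac_highN: float = 0.05
    lof_categories: frozenset = field(default_factory=lambda: DEFAULT_LOF_CATEGORIES)
    verbosity: int = logging.INFO

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path | None = None) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        sim_doc = doc.get("sim")
        if sim_doc is None:
            sim = default_sim_config(seed=int(doc.get("seed", 0)))
        else:
            tmp = Path(path).with_suffix(".sim.tmp.yaml")
            tmp.write_text(yaml.safe_dump(sim_doc))
            try:
                sim = SimConfig.from_yaml(tmp)
            finally:
                tmp.unlink(missing_ok=True)
        kwargs = {
            k: doc[k]
            for k in (
                "em_tol", "em_max_iter", "n_select", "n_reference",
                "common_freq_threshold", "adapter", "n_reads", "read_len",
                "frac_adapter", "frac_lowq", "frac_highN",
            )
            if k in doc
        }
        if "lof_categories" in doc:
            kwargs["lof_categories"] = frozenset(doc["lof_categories"])
        out = Path(out_dir) if out_dir is not None else Path(doc.get("out_dir", "run"))
        return cls(sim=sim, out_dir=out, **kwargs)


def _jsonable(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _jsonable(float(obj))
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to disk).

    Outputs under ``cfg.out_dir``: genotypes.tsv, truth.tsv, panel.tsv,
    freqs.tsv, phased.tsv, assoc.tsv, selected.tsv, variants.vcf,
    annotation.tsv, cohorts.tsv, reads.fastq, clean.fastq, summary.json and
    run.log.  Any stage error aborts with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("hapburden")
    root.addHandler(handler)
    root.setLevel(cfg.verbosity)
    summary: dict = {"seed": cfg.sim.seed, "stages": []}

    def stage(name):
        logger.info("stage %s started", name)
        summary["stages"].append(name)
        return time.time()

    try:
        # ------------------------------------------------------ simulate
        t = stage("simulate")
        try:
            gm, truth = simulate_cohort_genotypes(cfg.sim)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        io_formats.write_panel(cfg.sim.panel, out / "panel.tsv")
        io_formats.write_genotype_table(gm, out / "genotypes.tsv")
        with (out / "truth.tsv").open("w") as fh:
            fh.write("sample_id\thap1\thap2\n")
            for sid, (h1, h2) in zip(gm.sample_ids, truth):
                fh.write(f"{sid}\t{h1}\t{h2}\n")
        logger.info("simulate done in %.2fs", time.time() - t)

        # --------------------------------------------------------- phase
        t = stage("phase")
        try:
            gm_in = io_formats.read_genotype_table(out / "genotypes.tsv", cfg.sim.panel)
            ft, pc = em_estimate(gm_in, tol=cfg.em_tol, max_iter=cfg.em_max_iter)
        except (OSError, io_formats.FormatError, ValueError) as exc:
            raise PipelineError("phase", str(exc)) from exc
        write_freq_table(ft, out / "freqs.tsv")
        write_phased(pc, out / "phased.tsv")
        summary["phasing"] = {
            "log_likelihood": pc.log_likelihood,
            "n_iter": pc.n_iter,
            "converged": pc.converged,
            "n_excluded_missing": pc.n_excluded_missing,
            "n_haplotypes": len(ft),
        }
        summary["haplotype_freqs"] = _jsonable(ft.to_dataframe().to_dict("records"))
        logger.info("phase done in %.2fs", time.time() - t)

        # --------------------------------------------------------- assoc
        t = stage("assoc")
        dosages = haplotypes_to_biallelic(pc, ft)
        cohorts = [a.cohort for a in pc.assignments]
        scan = haplotype_assoc_scan(dosages, cohorts)
        scan_df = scan_to_dataframe(scan)
        scan_df.to_csv(out / "assoc.tsv", sep="\t", index=False)
        summary["haplotype_assoc"] = _jsonable(scan_df.to_dict("records"))
        defined = [(h, r) for h, r in scan if not math.isnan(r.p)]
        if not defined:
            raise PipelineError("assoc", "no haplotype has a defined association test")
        target_hap = defined[0][0]
        summary["target_hap"] = target_hap
        logger.info("assoc done in %.2fs; target haplotype %s", time.time() - t, target_hap)

        # -------------------------------------------------------- select
        t = stage("select")
        sel_cfg = SelectionConfig(
            target_hap=target_hap,
            n_total=cfg.n_select,
            common_freq_threshold=cfg.common_freq_threshold,
            n_reference=cfg.n_reference,
        )
        try:
            selected = select_sequencing_samples(pc, ft, sel_cfg)
        except (KeyError, ValueError) as exc:
            raise PipelineError("select", str(exc)) from exc
        with (out / "selected.tsv").open("w") as fh:
            fh.write("sample_id\tcohort\thap1\thap2\treason\n")
            for s in selected:
                fh.write(
                    f"{s.sample_id}\t{s.cohort}\t{s.diplotype[0]}\t"
                    f"{s.diplotype[1]}\t{s.selection_reason}\n"
                )
        summary["selected"] = [
            {
                "sample_id": s.sample_id,
                "cohort": s.cohort,
                "diplotype": list(s.diplotype),
                "reason": s.selection_reason,
            }
            for s in selected
        ]
        logger.info("select done in %.2fs (%d samples)", time.time() - t, len(selected))

        # ------------------------------------------- sequencing simulation
        t = stage("sequence")
        sel_ids = [s.sample_id for s in selected]
        idx = {sid: i for i, sid in enumerate(gm.sample_ids)}
        sel_samples = [(s.sample_id, s.cohort) for s in selected]
        sel_truth = [truth[idx[sid]] for sid in sel_ids]
        try:
            vt = simulate_lof_variants(cfg.sim, sel_samples, sel_truth)
        except Exception as exc:
            raise PipelineError("sequence", str(exc)) from exc
        io_formats.write_vcf(vt, out / "variants.vcf")
        io_formats.write_annotation_table(vt, out / "annotation.tsv")
        io_formats.write_cohort_table(vt.sample_ids, vt.cohorts, out / "cohorts.tsv")
        rs, read_truth = simulate_reads(
            cfg.n_reads,
            cfg.read_len,
            cfg.adapter,
            cfg.frac_adapter,
            cfg.frac_lowq,
            cfg.frac_highN,
            seed=cfg.sim.seed,
        )
        io_formats.write_fastq(rs, out / "reads.fastq")
        logger.info("sequence done in %.2fs", time.time() - t)

        # -------------------------------------------------------- readqc
        t = stage("readqc")
        rs_in = io_formats.read_fastq(out / "reads.fastq")
        clean, report = filter_reads(rs_in, adapter=cfg.adapter)
        io_formats.write_fastq(clean, out / "clean.fastq")
        summary["readqc"] = _jsonable(report.to_dict())
        n_true_violations = sum(1 for v in read_truth.values() if v is not None)
        if report.n_raw - report.n_clean != n_true_violations:
            raise PipelineError("readqc", "filter disagrees with simulation ground truth")
        logger.info("readqc done in %.2fs", time.time() - t)

        # ------------------------------------------------- classify_lof
        t = stage("classify_lof")
        vt_in = io_formats.read_variant_table(
            out / "variants.vcf", out / "annotation.tsv", out / "cohorts.tsv"
        )
        lof = classify_lof(vt_in, cfg.lof_categories)
        summary["n_lof_sites"] = lof.n_sites
        logger.info("classify_lof done in %.2fs", time.time() - t)

        # --------------------------------------------------------- coseg
        t = stage("coseg")
        sel_pc = PhasedCohort(
            assignments=[a for a in pc.assignments if a.sample_id in set(sel_ids)],
            log_likelihood=pc.log_likelihood,
            n_iter=pc.n_iter,
            converged=pc.converged,
        )
        sel_dosages = haplotypes_to_biallelic(sel_pc, ft)
        target_vec = {
            sid: int(sel_dosages.loc[sid, target_hap]) for sid in lof.sample_ids
        }
        hits = coseg_scan(lof, target_vec, target_hap=target_hap)
        summary["coseg_hits"] = [
            {"site_id": h.site_id, "gene": h.gene, "target_hap": h.target_hap}
            for h in hits
        ]
        logger.info("coseg done in %.2fs (%d hit(s))", time.time() - t, len(hits))

        # -------------------------------------------------------- burden
        t = stage("burden")
        rows = gene_burden_scan(lof)
        burden_df = burden_to_dataframe(rows)
        burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)
        summary["gene_burden"] = _jsonable(burden_df.to_dict("records"))
        logger.info("burden done in %.2fs", time.time() - t)

        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
        )
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
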