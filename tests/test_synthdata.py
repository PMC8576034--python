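"""Synthetic-data generator: determinism, sampling structure, ground truth."""

import numpy as np
import pytest
from scipy.stats import chisquare

from hapburden.io_formats import write_fastq, read_fastq
from hapburden.synthdata import (
    ConfigError,
    LofSiteSpec,
    SimConfig,
    default_sim_config,
    simulate_cohort_genotypes,
    simulate_lof_variants,
    simulate_reads,
)


def two_hap_config(panel3, f1=0.7, n_case=50, n_control=50, seed=0, **kw):
    h1 = panel3.haplotype_string((0, 0, 0))
    h2 = panel3.haplotype_string((1, 1, 1))
    freqs = {h1: f1, h2: 1.0 - f1}
    return SimConfig(
        panel=panel3,
        hap_freqs_case=dict(freqs),
        hap_freqs_control=dict(freqs),
        n_case=n_case,
        n_control=n_control,
        seed=seed,
        **kw,
    )


class TestSimConfig:
    def test_frequencies_must_sum_to_one(self, panel3):
        with pytest.raises(ConfigError, match="sum"):
            SimConfig(
                panel=panel3,
                hap_freqs_case={"GCC": 0.5, "AT-": 0.4},
                hap_freqs_control={"GCC": 1.0},
                n_case=2,
                n_control=2,
            )

    def test_invalid_haplotype_string_rejected(self, panel3):
        with pytest.raises(ValueError):
            SimConfig(
                panel=panel3,
                hap_freqs_case={"XXX": 1.0},
                hap_freqs_control={"GCC": 1.0},
                n_case=2,
                n_control=2,
            )

    def test_coseg_target_must_be_panel_haplotype(self, panel3):
        with pytest.raises(ConfigError, match="coseg_target"):
            two_hap_config(panel3, coseg_target="ZZZ")

    def test_yaml_roundtrip(self, tmp_path):
        cfg = default_sim_config(n_case=10, n_control=20, seed=5)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimConfig.from_yaml(tmp_path / "sim.yaml")
        assert back.panel == cfg.panel
        assert back.hap_freqs_case == cfg.hap_freqs_case
        assert back.lof_spec == cfg.lof_spec
        assert (back.n_case, back.n_control, back.seed) == (10, 20, 5)


class TestCohortGenotypes:
    def test_degenerate_distribution_all_homozygous(self, panel3):
        h = panel3.haplotype_string((1, 0, 1))
        cfg = SimConfig(
            panel=panel3,
            hap_freqs_case={h: 1.0},
            hap_freqs_control={h: 1.0},
            n_case=5,
            n_control=5,
        )
        gm, truth = simulate_cohort_genotypes(cfg)
        assert all(pair == (h, h) for pair in truth)
        assert np.array_equal(gm.dosage, np.tile([2, 0, 2], (10, 1)))

    def test_empirical_frequency_within_three_se(self, panel3):
        # binomial sampling bound: se = sqrt(0.7*0.3/4000) ~ 0.0072
        cfg = two_hap_config(panel3, f1=0.7, n_case=2000, n_control=1, seed=42)
        _, truth = simulate_cohort_genotypes(cfg)
        h1 = panel3.haplotype_string((0, 0, 0))
        case_haps = [h for pair in truth[:2000] for h in pair]
        freq = case_haps.count(h1) / 4000
        assert abs(freq - 0.7) < 3 * np.sqrt(0.7 * 0.3 / 4000)

    def test_determinism_bit_identical(self, panel3):
        cfg = two_hap_config(panel3, seed=9)
        gm1, t1 = simulate_cohort_genotypes(cfg)
        gm2, t2 = simulate_cohort_genotypes(cfg)
        assert np.array_equal(gm1.dosage, gm2.dosage)
        assert t1 == t2 and gm1.sample_ids == gm2.sample_ids

    def test_hardy_weinberg_within_cohort(self, panel3):
        """Diplotype class counts fit HW proportions (chi2 GOF, alpha=0.01,
        at most 2 rejections tolerated across 20 seeds)."""
        h1 = panel3.haplotype_string((0, 0, 0))
        f = 0.6
        rejections = 0
        for seed in range(20):
            cfg = two_hap_config(panel3, f1=f, n_case=500, n_control=1, seed=seed)
            _, truth = simulate_cohort_genotypes(cfg)
            counts = [0, 0, 0]  # hom h1, het, hom h2
            for a, b in truth[:500]:
                counts[(a != h1) + (b != h1)] += 1
            expected = np.array([f * f, 2 * f * (1 - f), (1 - f) ** 2]) * 500
            _, p = chisquare(counts, expected)
            rejections += p < 0.01
        assert rejections <= 2


class TestLofVariants:
    def test_allele_total_structure(self, panel3):
        # 12 sites x 8 samples per cohort -> per-cohort Alt+Ref = 192,
        # matching the published TMEM232 row structure (20+172 = 50+142)
        lof = {
            "TMEM232": [
                LofSiteSpec(f"s{k}", 0.10, 0.26, "exonic") for k in range(12)
            ]
        }
        cfg = two_hap_config(panel3, n_case=8, n_control=8, lof_spec=lof)
        gm, truth = simulate_cohort_genotypes(cfg)
        vt = simulate_lof_variants(cfg, list(zip(gm.sample_ids, gm.cohorts)), truth)
        is_case = np.array([c == "case" for c in vt.cohorts])
        alt_case = int(vt.dosage[:, is_case].sum())
        alt_ctrl = int(vt.dosage[:, ~is_case].sum())
        assert alt_case + (2 * 8 * 12 - alt_case) == 192
        assert alt_ctrl + (2 * 8 * 12 - alt_ctrl) == 192
        assert vt.n_sites == 12

    def test_zero_alt_freq_gives_zero_alt_count(self, panel3):
        lof = {"G1": [LofSiteSpec(f"s{k}", 0.0, 0.5, "exonic") for k in range(3)]}
        cfg = two_hap_config(panel3, n_case=20, n_control=20, lof_spec=lof, seed=3)
        gm, truth = simulate_cohort_genotypes(cfg)
        vt = simulate_lof_variants(cfg, list(zip(gm.sample_ids, gm.cohorts)), truth)
        is_case = np.array([c == "case" for c in vt.cohorts])
        assert vt.dosage[:, is_case].sum() == 0
        assert vt.dosage[:, ~is_case].sum() > 0

    def test_planted_site_tracks_target_copy_number(self, panel3):
        target = panel3.haplotype_string((1, 1, 1))
        lof = {"G1": [LofSiteSpec("s1", 0.2, 0.2, "exonic")]}
        cfg = two_hap_config(
            panel3, n_case=30, n_control=30, lof_spec=lof,
            coseg_target=target, coseg_gene="G1", seed=4,
        )
        gm, truth = simulate_cohort_genotypes(cfg)
        vt = simulate_lof_variants(cfg, list(zip(gm.sample_ids, gm.cohorts)), truth)
        planted = [i for i, s in enumerate(vt.sites) if s.site_id == "G1_coseg"]
        assert len(planted) == 1
        expected = [(a == target) + (b == target) for a, b in truth]
        assert vt.dosage[planted[0]].tolist() == expected


class TestReads:
    def test_no_violations_configured(self):
        rs, truth = simulate_reads(50, 80, "ACGTACGTACGT", seed=1)
        assert len(rs) == 50
        assert all(v is None for v in truth.values())

    def test_exact_adapter_count(self):
        adapter = "AGATCGGAAGAGC"
        rs, truth = simulate_reads(
            100, 100, adapter, frac_adapter=0.1, seed=2
        )
        containing = [r.read_id for r in rs if adapter in r.bases]
        labelled = [rid for rid, v in truth.items() if v == "adapter"]
        assert len(containing) == 10
        assert sorted(containing) == sorted(labelled)

    def test_all_low_quality(self):
        rs, truth = simulate_reads(20, 60, "ACGTACGT", frac_lowq=1.0, seed=3)
        assert all(v == "low_quality" for v in truth.values())
        for r in rs:
            assert sum(q <= 5 for q in r.quals) > 0.5 * len(r.quals)

    def test_adapter_longer_than_read_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            simulate_reads(10, 5, "ACGTACGTAC", frac_adapter=0.5)

    def test_determinism_and_fastq_roundtrip(self, tmp_path):
        rs1, t1 = simulate_reads(30, 50, "ACGTACGT", 0.1, 0.1, 0.1, seed=7)
        rs2, t2 = simulate_reads(30, 50, "ACGTACGT", 0.1, 0.1, 0.1, seed=7)
        assert t1 == t2
        assert [(r.read_id, r.bases, r.quals) for r in rs1] == [
            (r.read_id, r.bases, r.quals) for r in rs2
        ]
        write_fastq(rs1, tmp_path / "r.fastq")
        back = read_fastq(tmp_path / "r.fastq")
        assert [(r.read_id, r.bases, r.quals) for r in back] == [
            (r.read_id, r.bases, r.quals) for r in rs1
        ]
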