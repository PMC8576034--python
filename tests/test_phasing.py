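"""EM phaser: enumeration combinatorics, oracle equivalence, recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import identified_instance, oracle_loglik, _pair_lists
from hapburden.io_formats import GenotypeMatrix, MISSING
from hapburden.phasing import (
    HaplotypeFreq,
    HaplotypeFreqTable,
    em_estimate,
    enumerate_pairs,
    label_haplotypes,
    read_freq_table,
    read_phased,
    write_freq_table,
    write_phased,
)
from hapburden.synthdata import SimConfig, simulate_cohort_genotypes


def make_gm(panel, rows, cohorts=None):
    rows = np.asarray(rows, dtype=np.int8)
    n = rows.shape[0]
    return GenotypeMatrix(
        panel=panel,
        sample_ids=[f"S{i}" for i in range(n)],
        cohorts=cohorts or ["case"] * n,
        dosage=rows,
    )


class TestEnumeratePairs:
    def test_homozygous_gives_single_diplotype(self):
        assert enumerate_pairs([0, 2, 0]) == [((0, 1, 0), (0, 1, 0))]

    def test_two_het_classic_ambiguity(self):
        pairs = enumerate_pairs([1, 1, 0])
        assert len(pairs) == 2
        assert set(pairs) == {
            ((0, 0, 0), (1, 1, 0)),
            ((0, 1, 0), (1, 0, 0)),
        }

    def test_ten_het_gives_512(self):
        assert len(enumerate_pairs([1] * 10)) == 512

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        genotype=st.lists(st.integers(0, 2), min_size=1, max_size=8)
    )
    def test_pairs_reproduce_genotype_and_count(self, genotype):
        pairs = enumerate_pairs(genotype)
        h = sum(g == 1 for g in genotype)
        assert len(pairs) == (2 ** (h - 1) if h else 1)
        assert len(set(pairs)) == len(pairs)
        for a, b in pairs:
            assert [x + y for x, y in zip(a, b)] == list(genotype)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs([0, MISSING, 1])


class TestEmEstimate:
    def test_unambiguous_cohort_equals_direct_counting(self, panel3):
        # 4x hom(0,0,0), 2x hom(1,1,1): freqs must be 0.75/0.25 exactly
        gm = make_gm(panel3, [[0, 0, 0]] * 4 + [[2, 2, 2]] * 2)
        ft, pc = em_estimate(gm)
        assert pc.converged
        ref = panel3.haplotype_string((0, 0, 0))
        alt = panel3.haplotype_string((1, 1, 1))
        assert ft.by_string(ref).freq_pooled == pytest.approx(4 / 6, abs=1e-12)
        assert ft.by_string(alt).freq_pooled == pytest.approx(2 / 6, abs=1e-12)
        assert all(a.posterior == pytest.approx(1.0) for a in pc.assignments)

    def test_matches_exhaustive_oracle_small_instances(self, panel3):
        rng = np.random.default_rng(12)
        for trial in range(20):
            rows, haps, f_oracle, ll_oracle = identified_instance(
                panel3, rng, seed=trial
            )
            gm = make_gm(panel3, rows)
            ft, _ = em_estimate(gm, tol=1e-12, max_iter=5000)
            f_em = np.zeros(len(haps))
            for k, mask in enumerate(haps):
                s = panel3.haplotype_string(mask)
                try:
                    f_em[k] = ft.by_string(s).freq_pooled
                except KeyError:
                    pass
            tv = 0.5 * np.abs(f_em - f_oracle).sum()
            _, per_row = _pair_lists(rows)
            ll_em = oracle_loglik(np.clip(f_em, 1e-300, None), per_row)
            assert ll_em >= ll_oracle - 1e-6
            assert tv < 1e-4

    def test_recovers_known_frequencies(self, panel10):
        from hapburden.reference import COMMON_HAPLOTYPES

        strings = [COMMON_HAPLOTYPES[h][0] for h in ("H62", "H14", "H43", "H56")]
        truth_f = dict(zip(strings, (0.55, 0.25, 0.15, 0.05)))
        cfg = SimConfig(
            panel=panel10,
            hap_freqs_case=dict(truth_f),
            hap_freqs_control=dict(truth_f),
            n_case=1000,
            n_control=1000,
            seed=21,
        )
        gm, _ = simulate_cohort_genotypes(cfg)
        ft, pc = em_estimate(gm)
        est = {e.allele_string: e.freq_pooled for e in ft}
        rmse = np.sqrt(
            np.mean([(est.get(s, 0.0) - f) ** 2 for s, f in truth_f.items()])
        )
        assert rmse < 0.02
        assert pc.converged

    def test_cohort_columns_reflect_cohort_composition(self, panel3):
        # cases carry only hap A, controls only hap B
        gm = make_gm(
            panel3,
            [[0, 0, 0]] * 5 + [[2, 2, 2]] * 5,
            cohorts=["case"] * 5 + ["control"] * 5,
        )
        ft, _ = em_estimate(gm)
        a = ft.by_string(panel3.haplotype_string((0, 0, 0)))
        b = ft.by_string(panel3.haplotype_string((1, 1, 1)))
        assert a.freq_case == pytest.approx(1.0) and a.freq_control == pytest.approx(0.0)
        assert b.freq_case == pytest.approx(0.0) and b.freq_control == pytest.approx(1.0)
        assert a.freq_pooled == pytest.approx(0.5)

    def test_missing_individuals_excluded_with_count(self, panel3):
        gm = make_gm(panel3, [[0, 0, 0], [MISSING, 0, 0], [2, 2, 2]])
        ft, pc = em_estimate(gm)
        assert pc.n_excluded_missing == 1
        assert len(pc.assignments) == 2

    def test_all_missing_raises(self, panel3):
        gm = make_gm(panel3, [[MISSING, 0, 0]])
        with pytest.raises(ValueError, match="no individuals"):
            em_estimate(gm)

    def test_equal_posterior_tie_broken_lexicographically(self, panel3):
        # one homozygote per haplotype pins symmetric frequencies, so the
        # double-heterozygote's two phasings tie at posterior 0.5 and the
        # lexicographically smaller allele-string pair must be chosen
        gm = make_gm(
            panel3,
            [[1, 1, 0], [0, 0, 0], [2, 2, 0], [0, 2, 0], [2, 0, 0]],
        )
        ft, pc = em_estimate(gm)
        asn = pc.assignments[0]
        s1 = ft.by_id(asn.hap1).allele_string
        s2 = ft.by_id(asn.hap2).allele_string
        # candidate pairs: {GCC,ATC} and {ACC,GTC}; min sorted pair is (ACC,GTC)
        assert (s1, s2) == ("ACC", "GTC")
        assert asn.posterior == pytest.approx(0.5)

    def test_simplex_and_determinism(self, panel10):
        cfg = SimConfig(
            panel=panel10,
            hap_freqs_case={"GCCTGGCGAT": 0.5, "----AA-AG-": 0.5},
            hap_freqs_control={"GCCTGGCGAT": 0.3, "----AA-AG-": 0.7},
            n_case=100,
            n_control=100,
            seed=5,
        )
        gm, _ = simulate_cohort_genotypes(cfg)
        ft1, pc1 = em_estimate(gm)
        ft2, pc2 = em_estimate(gm)
        assert ft1.to_dataframe().equals(ft2.to_dataframe())
        assert pc1.to_dataframe().equals(pc2.to_dataframe())
        for col in ("freq_case", "freq_control", "freq_pooled"):
            assert ft1.to_dataframe()[col].sum() == pytest.approx(1.0, abs=1e-6)


class TestLabelHaplotypes:
    def table(self, strings):
        return HaplotypeFreqTable(
            entries=[
                HaplotypeFreq(f"X{i}", s, 0.0, 0.0, 1.0 / len(strings))
                for i, s in enumerate(strings)
            ]
        )

    def test_lexicographic_labels(self):
        ft = label_haplotypes(self.table(["GA", "AC"]))
        assert [(e.hap_id, e.allele_string) for e in ft] == [
            ("H1", "AC"),
            ("H2", "GA"),
        ]

    def test_single_haplotype(self):
        ft = label_haplotypes(self.table(["GG"]))
        assert ft.entries[0].hap_id == "H1"

    def test_idempotent(self):
        once = label_haplotypes(self.table(["GA", "AC", "CC"]))
        twice = label_haplotypes(once)
        assert once == twice


class TestTableIO:
    def test_freq_and_phased_roundtrip(self, tmp_path, panel3):
        gm = make_gm(panel3, [[1, 1, 0], [0, 0, 0], [2, 2, 2]])
        ft, pc = em_estimate(gm)
        write_freq_table(ft, tmp_path / "f.tsv")
        write_phased(pc, tmp_path / "p.tsv")
        ft2 = read_freq_table(tmp_path / "f.tsv")
        pc2 = read_phased(tmp_path / "p.tsv")
        pd.testing.assert_frame_equal(
            ft2.to_dataframe(), ft.to_dataframe(), rtol=1e-12
        )
        assert [
            (a.sample_id, a.cohort, a.hap1, a.hap2) for a in pc2.assignments
        ] == [(a.sample_id, a.cohort, a.hap1, a.hap2) for a in pc.assignments]
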