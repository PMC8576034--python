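"""2x2 association statistics, haplotype scan, LD r-squared."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hapburden.hapassoc import (
    assoc_2x2,
    assoc_from_freqs,
    dosage_matrix_from_pairs,
    haplotype_assoc_scan,
    haplotypes_to_biallelic,
    pairwise_r2,
)
from hapburden.phasing import (
    DiplotypeAssignment,
    HaplotypeFreq,
    HaplotypeFreqTable,
    PhasedCohort,
)


class TestAssoc2x2:
    @pytest.mark.parametrize(
        "counts, chi2, or_, ci",
        [
            # published gene-level rows, recomputed and verified exactly
            ((20, 172, 50, 142), 15.72, 0.33, (0.19, 0.58)),
            ((23, 73, 24, 72), 0.03, 0.95, (0.49, 1.83)),
            ((4, 28, 7, 25), 0.99, 0.51, (0.13, 1.95)),
            ((24, 120, 20, 124), 0.43, 1.24, (0.65, 2.36)),
            ((6, 106, 5, 107), 0.10, 1.21, (0.36, 4.09)),
        ],
    )
    def test_published_rows_reproduced(self, counts, chi2, or_, ci):
        r = assoc_2x2(*counts)
        assert round(r.chi2, 2) == chi2
        assert round(r.or_, 2) == or_
        assert (round(r.ci_low, 2), round(r.ci_high, 2)) == ci

    def test_symmetric_table_null(self):
        r = assoc_2x2(10, 90, 10, 90)
        assert r.chi2 == pytest.approx(0.0)
        assert r.or_ == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_zero_cell_or_undefined_chi2_defined(self):
        r = assoc_2x2(0, 100, 10, 90)
        assert math.isnan(r.or_) and math.isnan(r.ci_low)
        assert not math.isnan(r.chi2) and not math.isnan(r.p)

    def test_empty_allele_margin_all_na(self):
        r = assoc_2x2(0, 100, 0, 100)  # a+c == 0
        assert math.isnan(r.chi2) and math.isnan(r.p) and math.isnan(r.or_)
        assert r.maf_case == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            assoc_2x2(-1, 2, 3, 4)

    def test_yates_correction_smaller_chi2(self):
        plain = assoc_2x2(20, 172, 50, 142)
        corrected = assoc_2x2(20, 172, 50, 142, yates=True)
        assert corrected.chi2 < plain.chi2

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
    )
    def test_row_swap_inverts_or_keeps_chi2(self, a, b, c, d):
        r1 = assoc_2x2(a, b, c, d)
        r2 = assoc_2x2(c, d, a, b)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-12)
        assert r1.or_ == pytest.approx(1.0 / r2.or_, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.integers(1, 300), b=st.integers(1, 300),
        c=st.integers(1, 300), d=st.integers(1, 300),
    )
    def test_chi2_equals_squared_two_proportion_z(self, a, b, c, d):
        r = assoc_2x2(a, b, c, d)
        n1, n2 = a + b, c + d
        p1, p2 = a / n1, c / n2
        p_pool = (a + c) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(p_pool * (1 - p_pool) * (1 / n1 + 1 / n2))
        assert r.chi2 == pytest.approx(z * z, rel=1e-10)


class TestAssocFromFreqs:
    @pytest.mark.parametrize(
        "f_case, f_control, expected",
        [
            (0.0016, 0.0094, 0.17),  # top-associated haplotype headline OR
            (0.2319, 0.2415, 0.95),  # most frequent haplotype
            (0.068, 0.0552, 1.25),
            (0.0412, 0.0372, 1.11),
        ],
    )
    def test_published_frequency_ors(self, f_case, f_control, expected):
        assert round(assoc_from_freqs(f_case, f_control), 2) == expected

    def test_identity_at_equal_frequencies(self):
        for x in (0.01, 0.3, 0.77):
            assert assoc_from_freqs(x, x) == pytest.approx(1.0)

    def test_boundary_undefined(self):
        assert math.isnan(assoc_from_freqs(0.0, 0.5))
        assert math.isnan(assoc_from_freqs(0.5, 1.0))

    def test_agrees_with_count_parameterisation(self):
        f1, f2, n1, n2 = 0.1, 0.25, 200, 400
        counted = assoc_2x2(
            f1 * 2 * n1, (1 - f1) * 2 * n1, f2 * 2 * n2, (1 - f2) * 2 * n2
        )
        assert assoc_from_freqs(f1, f2) == pytest.approx(counted.or_, rel=1e-12)


def make_phased(assignments):
    return PhasedCohort(
        assignments=[
            DiplotypeAssignment(f"S{i}", cohort, h1, h2, 1.0)
            for i, (cohort, h1, h2) in enumerate(assignments)
        ],
        log_likelihood=0.0,
        n_iter=1,
        converged=True,
    )


def make_table(ids_strings):
    k = len(ids_strings)
    return HaplotypeFreqTable(
        entries=[HaplotypeFreq(h, s, 1 / k, 1 / k, 1 / k) for h, s in ids_strings]
    )


class TestDosagesAndScan:
    def test_dosage_from_assignments(self):
        pc = make_phased([("case", "H15", "H62"), ("case", "H15", "H15")])
        ft = make_table([("H15", "AA"), ("H62", "GG"), ("H99", "AG")])
        d = haplotypes_to_biallelic(pc, ft)
        assert d.loc["S0"].tolist() == [1, 1, 0]
        assert d.loc["S1"].tolist() == [2, 0, 0]
        assert (d.sum(axis=1) == 2).all()

    def test_scan_counts_and_conservation(self):
        pc = make_phased(
            [
                ("case", "H1", "H1"),
                ("case", "H1", "H2"),
                ("control", "H2", "H2"),
                ("control", "H1", "H2"),
            ]
        )
        ft = make_table([("H1", "AA"), ("H2", "GG")])
        d = haplotypes_to_biallelic(pc, ft)
        scan = dict(haplotype_assoc_scan(d, [a.cohort for a in pc.assignments]))
        r1 = scan["H1"]
        assert (r1.a, r1.b, r1.c, r1.d) == (3, 1, 1, 3)
        n_case = 2
        assert sum(r.a for r in scan.values()) == 2 * n_case
        assert sum(r.c for r in scan.values()) == 2 * n_case

    def test_complete_separation_row(self):
        pc = make_phased(
            [("case", "H1", "H1")] * 3 + [("control", "H2", "H2")] * 3
        )
        ft = make_table([("H1", "AA"), ("H2", "GG")])
        d = haplotypes_to_biallelic(pc, ft)
        scan = dict(haplotype_assoc_scan(d, [a.cohort for a in pc.assignments]))
        r = scan["H1"]
        assert r.b == 0 and r.c == 0
        assert math.isnan(r.or_)
        assert r.chi2 == pytest.approx(12.0)  # maximal for 2x6/2x6 table

    def test_sorted_by_p_and_bonferroni(self):
        pc = make_phased(
            [("case", "H1", "H1")] * 5
            + [("control", "H2", "H2")] * 5
            + [("case", "H3", "H3"), ("control", "H3", "H3")]
        )
        ft = make_table([("H1", "AA"), ("H2", "GG"), ("H3", "CC")])
        d = haplotypes_to_biallelic(pc, ft)
        cohorts = [a.cohort for a in pc.assignments]
        scan = haplotype_assoc_scan(d, cohorts)
        ps = [r.p for _, r in scan]
        assert ps == sorted(ps)
        adj = dict(haplotype_assoc_scan(d, cohorts, bonferroni=True))
        raw = dict(scan)
        for h in raw:
            assert adj[h].p == pytest.approx(min(1.0, raw[h].p * 3))

    def test_truth_pair_dosage_helper(self):
        d = dosage_matrix_from_pairs(
            [("A", "B"), ("B", "B")], ["S1", "S2"]
        )
        assert d.loc["S1"].tolist() == [1, 1]
        assert d.loc["S2"].tolist() == [0, 2]


class TestPairwiseR2:
    def test_perfect_correlation(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        assert pairwise_r2(x, x) == pytest.approx(1.0)
        assert pairwise_r2(x, 1 - x) == pytest.approx(1.0)

    def test_independent_at_expected_counts(self):
        # 2x2 haplotype counts exactly proportional -> D = 0
        x = np.array([1, 1, 0, 0])
        y = np.array([1, 0, 1, 0])
        assert pairwise_r2(x, y) == pytest.approx(0.0)

    def test_four_haplotype_toy(self):
        # counts AB:40, Ab:10, aB:10, ab:40 -> D = 0.15, denom = 0.0625
        x = np.array([1] * 50 + [0] * 50)
        y = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        assert pairwise_r2(x, y) == pytest.approx(0.36)

    def test_monomorphic_undefined(self):
        assert math.isnan(pairwise_r2([1, 1, 1], [0, 1, 0]))
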