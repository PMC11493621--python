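import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrmediate.instruments import (build_instrument_set, f_statistic,
                                   filter_weak, InstrumentSet, ld_clump,
                                   select_by_pvalue, snp_r2)
from mrmediate.sumstats import LDInfo
from conftest import make_trait


def trait(rows, trait_id="E"):
    return make_trait(rows, trait_id)


class TestPvalueSelection:
    def test_threshold_filters(self):
        t = trait([("rs1", "1", 100, "A", "G", 0.2, 0.1, 0.02, 1e-6, 5000),
                   ("rs2", "1", 200, "C", "T", 0.3, 0.1, 0.02, 1e-4, 5000)])
        assert select_by_pvalue(t, 1e-5).df["snp"].tolist() == ["rs1"]

    def test_threshold_one_keeps_all(self):
        t = trait([("rs1", "1", 100, "A", "G", 0.2, 0.1, 0.02, 1e-6, 5000),
                   ("rs2", "1", 200, "C", "T", 0.3, 0.1, 0.02, 0.9, 5000)])
        assert select_by_pvalue(t, 1.0).n_snps == 2

    def test_null_snps_essentially_never_selected(self, rng):
        # uniform p-values at the suggestive threshold: expect ~100*1e-5
        rows = [(f"rs{i}", "1", i, "A", "G", 0.2, 0.0, 0.02,
                 rng.uniform(), 5000) for i in range(100)]
        assert select_by_pvalue(trait(rows), 1e-5).n_snps == 0


class TestClumping:
    def make_ld(self, pairs):
        ld = LDInfo()
        for a, b, r2 in pairs:
            ld.set_r2(a, b, r2)
        return ld

    def test_hand_traced_greedy(self):
        t = trait([("a", "1", 10_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                   ("b", "1", 15_000, "C", "T", 0.3, 0.1, 0.02, 1e-6, 5000)])
        ld = self.make_ld([("a", "b", 0.5)])
        assert ld_clump(t, ld).df["snp"].tolist() == ["a"]

    def test_different_chromosomes_never_clump(self):
        t = trait([("a", "1", 10_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                   ("b", "2", 10_000, "C", "T", 0.3, 0.1, 0.02, 1e-6, 5000)])
        ld = self.make_ld([("a", "b", 0.9)])
        assert ld_clump(t, ld).n_snps == 2

    def test_outside_window_kept(self):
        t = trait([("a", "1", 1_000_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                   ("b", "1", 20_000_000, "C", "T", 0.3, 0.1, 0.02, 1e-6, 5000)])
        ld = self.make_ld([("a", "b", 0.9)])
        assert ld_clump(t, ld).n_snps == 2

    def test_absent_ld_pair_treated_as_independent(self):
        t = trait([("a", "1", 10_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                   ("b", "1", 15_000, "C", "T", 0.3, 0.1, 0.02, 1e-6, 5000)])
        assert ld_clump(t, LDInfo()).n_snps == 2

    def test_empty_table(self):
        t = trait([("a", "1", 1, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000)])
        empty = select_by_pvalue(t, 1e-20)
        assert ld_clump(empty, LDInfo()).n_snps == 0

    def test_row_order_invariance(self):
        rows = [("a", "1", 10_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                ("b", "1", 15_000, "C", "T", 0.3, 0.1, 0.02, 1e-6, 5000),
                ("c", "1", 18_000, "G", "A", 0.3, 0.1, 0.02, 1e-7, 5000)]
        ld = self.make_ld([("a", "b", 0.5), ("b", "c", 0.9)])
        kept1 = set(ld_clump(trait(rows), ld).df["snp"])
        kept2 = set(ld_clump(trait(rows[::-1]), ld).df["snp"])
        assert kept1 == kept2

    def test_pvalue_tie_broken_by_snp_id(self):
        rows = [("z", "1", 10_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                ("a", "1", 15_000, "C", "T", 0.3, 0.1, 0.02, 1e-8, 5000)]
        ld = self.make_ld([("a", "z", 0.9)])
        assert ld_clump(trait(rows), ld).df["snp"].tolist() == ["a"]

    def test_stricter_r2_threshold_keeps_fewer_or_equal(self):
        rows = [("a", "1", 10_000, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000),
                ("b", "1", 15_000, "C", "T", 0.3, 0.1, 0.02, 1e-6, 5000),
                ("c", "1", 18_000, "G", "A", 0.3, 0.1, 0.02, 1e-7, 5000)]
        ld = self.make_ld([("a", "b", 0.05), ("a", "c", 0.3)])
        for loose, strict in [(0.5, 0.1), (0.1, 0.01)]:
            n_loose = ld_clump(trait(rows), ld, r2_threshold=loose).n_snps
            n_strict = ld_clump(trait(rows), ld, r2_threshold=strict).n_snps
            assert n_strict <= n_loose


class TestVarianceExplained:
    def test_formula_values(self):
        assert snp_r2(0.5, 0.1) == pytest.approx(0.005, rel=1e-12)
        assert snp_r2(0.3, 0.0) == 0.0
        assert snp_r2(0.9, 0.2) == pytest.approx(0.0072, rel=1e-12)

    def test_maf_folding(self):
        assert snp_r2(0.9, 0.2) == pytest.approx(snp_r2(0.1, 0.2), rel=1e-12)

    def test_alternative_formula_exposed(self):
        assert snp_r2(0.5, 0.1, se=0.1, formula="beta_over_se") == \
            pytest.approx(0.5, rel=1e-12)

    def test_missing_or_invalid_eaf(self):
        with pytest.raises(ValueError):
            snp_r2(float("nan"), 0.1)
        with pytest.raises(ValueError):
            snp_r2(1.0, 0.1)


class TestFStatistic:
    def test_study_scale_value(self):
        # N=7738, k=10, summed R2=0.013
        expected = (7727 / 10) * (0.013 / 0.987)
        assert f_statistic(7738, 10, 0.013) == pytest.approx(expected,
                                                             rel=1e-12)

    def test_edge_values(self):
        assert f_statistic(7738, 10, 0.0) == 0.0
        assert f_statistic(3, 1, 0.5) == pytest.approx(1.0, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(7738, 10, 1.0)
        with pytest.raises(ValueError):
            f_statistic(11, 10, 0.1)

    @given(n=st.integers(50, 10_000), k=st.integers(1, 20),
           r2=st.floats(0.001, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_monotonicity(self, n, k, r2):
        if n <= k + 2:
            return
        f = f_statistic(n, k, r2)
        assert f_statistic(n + 1, k, r2) > f          # increasing in n
        assert f_statistic(n, k, min(r2 * 1.1, 0.99)) > f  # increasing in R2
        if n > k + 3:
            assert f_statistic(n, k + 1, r2) < f      # decreasing in k


class TestWeakFilter:
    def iv(self, f):
        t = trait([("a", "1", 1, "A", "G", 0.2, 0.1, 0.02, 1e-8, 5000)])
        return InstrumentSet("E", t, {"a": 0.005}, 0.005, f)

    def test_boundary_f_equal_threshold_retained(self):
        assert filter_weak(self.iv(10.0)).k == 1

    def test_below_threshold_excluded_with_reason(self):
        out = filter_weak(self.iv(9.99))
        assert out.k == 0 and out.exclusion_reason == "weak_instruments"

    def test_strong_set_unchanged(self):
        assert filter_weak(self.iv(10.18)).exclusion_reason is None


class TestFullSelection:
    def test_pipeline_integration(self):
        rows = [("a", "1", 10_000, "A", "G", 0.2, 0.3, 0.02, 1e-10, 7738),
                ("b", "1", 15_000, "C", "T", 0.3, 0.25, 0.02, 1e-8, 7738),
                ("c", "2", 10_000, "G", "A", 0.4, 0.2, 0.02, 1e-7, 7738),
                ("d", "2", 99_000, "G", "A", 0.4, 0.2, 0.02, 1e-3, 7738)]
        ld = LDInfo()
        ld.set_r2("a", "b", 0.8)
        iv = build_instrument_set(trait(rows), ld)
        assert set(iv.table.df["snp"]) == {"a", "c"}  # d fails p, b clumped
        r2_expected = snp_r2(0.2, 0.3) + snp_r2(0.4, 0.2)
        assert iv.r2_total == pytest.approx(r2_expected, rel=1e-12)
        assert iv.f_stat == pytest.approx(
            f_statistic(7738, 2, r2_expected), rel=1e-12)

    def test_no_instruments_reason(self):
        rows = [("a", "1", 1, "A", "G", 0.2, 0.0, 0.02, 0.5, 7738)]
        iv = build_instrument_set(trait(rows), LDInfo())
        assert iv.k == 0 and iv.exclusion_reason == "no_instruments"

    def test_weak_trait_excluded(self):
        # tiny effects: F far below 10 at this sample size
        rows = [(f"rs{i}", str(i % 22 + 1), 10_000 + i, "A", "G", 0.3,
                 0.01, 0.002, 1e-6, 200) for i in range(5)]
        iv = build_instrument_set(trait(rows), LDInfo())
        assert iv.exclusion_reason == "weak_instruments"
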