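"""Site filters: missingness, exact HWE, LD r2, thinning, composition."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import tiny_matrix
from fusionscan.sitefilters import (
    FilterConfigError,
    apply_site_filters,
    filter_by_missingness,
    hwe_exact_test,
    ld_r2,
)
from oracles import hwe_exact_enumeration


class TestMissingness:
    def test_threshold_is_inclusive(self):
        dos = np.zeros((10, 1), dtype=int)
        dos[:3, 0] = -1  # 3 of 10 missing
        G = tiny_matrix(dos)
        kept, _ = filter_by_missingness(G, 0.3)
        assert kept.n_loci == 1

    def test_zero_threshold_keeps_only_complete_loci(self):
        dos = np.array([[0, 0], [1, -1], [2, 0]])
        G = tiny_matrix(dos)
        kept, rep = filter_by_missingness(G, 0.0)
        assert kept.n_loci == 1
        assert rep.steps[0].n_removed == 1

    def test_report_counts_are_consistent(self):
        G = tiny_matrix(np.array([[0, -1, 1], [-1, -1, 2]]))
        kept, rep = filter_by_missingness(G, 0.5)
        s = rep.steps[0]
        assert s.n_in == 3 and s.n_out == kept.n_loci
        assert s.n_removed + s.n_out == s.n_in

    def test_low_missing_rate_survives_loose_threshold(self):
        """P(locus dropped at threshold 0.5 | rate 0.1, 20 samples) is the
        binomial tail P(X > 10), < 1e-5 — so all loci survive whp."""
        tail = stats.binom.sf(10, 20, 0.1)
        assert tail < 1e-5
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(20, 500))
        dos[rng.random((20, 500)) < 0.1] = -1
        kept, _ = filter_by_missingness(tiny_matrix(dos), 0.5)
        assert kept.n_loci == 500


class TestHweExact:
    @pytest.mark.parametrize(
        "counts,expected",
        [((1, 0, 1), Fraction(1, 3)), ((0, 2, 0), Fraction(1, 1))],
    )
    def test_enumerated_small_cases(self, counts, expected):
        assert hwe_exact_test(*counts) == pytest.approx(float(expected), abs=1e-12)
        assert hwe_exact_enumeration(*counts) == expected

    def test_perfect_hwe_at_n100(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_counts_undefined(self):
        assert np.isnan(hwe_exact_test(0, 0, 0))

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    def test_matches_full_enumeration_oracle(self, a, h, b):
        if a + h + b == 0 or a + h + b > 30:
            return
        exact = hwe_exact_enumeration(a, h, b)
        assert hwe_exact_test(a, h, b) == pytest.approx(float(exact), abs=1e-9)


class TestLdR2:
    def test_identical_and_inverted_vectors(self):
        assert ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)
        assert ld_r2([0, 0, 2, 2], [2, 2, 0, 0]) == pytest.approx(1.0)

    def test_matches_scipy_pearson(self):
        a, b = [0, 1, 2, 0, 1], [2, 0, 1, 1, 0]
        r, _ = stats.pearsonr(a, b)
        assert ld_r2(a, b) == pytest.approx(r**2, abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(ld_r2([1, 1, 1], [0, 1, 2]))

    def test_missing_entries_pairwise_deleted(self):
        a = [0, 1, 2, -1, 1]
        b = [0, 1, 2, 2, -1]
        assert ld_r2(a, b) == pytest.approx(1.0)


class TestThinningAndComposition:
    def test_close_pair_thinned_to_one(self):
        G = tiny_matrix(np.array([[0, 1], [1, 2]]))
        G.loci["pos"] = [100, 130]
        out, rep = apply_site_filters(G, [("thin_bp", {"min_bp": 50})], seed=0)
        assert out.n_loci == 1

    def test_distant_pair_both_retained(self):
        G = tiny_matrix(np.array([[0, 1], [1, 2]]))
        G.loci["pos"] = [100, 6000]
        out, _ = apply_site_filters(G, [("thin_bp", {"min_bp": 5000})], seed=0)
        assert out.n_loci == 2

    def test_thinning_random_choice_is_seeded(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(4, 40))
        G = tiny_matrix(dos)
        G.loci["pos"] = np.arange(40) * 30 + 1  # everything chained
        a, _ = apply_site_filters(G, [("thin_bp", {"min_bp": 50})], seed=7)
        b, _ = apply_site_filters(G, [("thin_bp", {"min_bp": 50})], seed=7)
        c, _ = apply_site_filters(G, [("thin_bp", {"min_bp": 50})], seed=8)
        assert a.loci.equals(b.loci)
        assert a.n_loci == 1
        assert c.n_loci == 1

    def test_ld_prune_removes_later_duplicate(self):
        dos = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1]])
        G = tiny_matrix(dos)
        G.loci["pos"] = [100, 300]  # 200 bp apart, duplicate dosages
        out, _ = apply_site_filters(
            G, [("ld_prune", {"r2_threshold": 0.8, "window_bp": 1000})], seed=0
        )
        assert out.n_loci == 1
        assert out.loci["pos"].tolist() == [100]

    def test_ld_prune_outside_window_untouched(self):
        dos = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1]])
        G = tiny_matrix(dos)
        G.loci["pos"] = [100, 2000]
        out, _ = apply_site_filters(
            G, [("ld_prune", {"r2_threshold": 0.8, "window_bp": 1000})], seed=0
        )
        assert out.n_loci == 2

    def test_hwe_filter_removes_violating_locus(self):
        # locus 0: all heterozygous (20 samples) -> tiny exact p
        dos = np.column_stack([np.ones(20, dtype=int),
                               np.repeat([0, 1, 2], [5, 10, 5])])
        G = tiny_matrix(dos)
        out, rep = apply_site_filters(G, [("hwe", {"alpha": 0.001})], seed=0)
        assert out.n_loci == 1
        assert rep.steps[0].n_removed == 1

    def test_unknown_filter_name_rejected(self):
        G = tiny_matrix(np.array([[0], [1]]))
        with pytest.raises(FilterConfigError, match="unknown filter"):
            apply_site_filters(G, [("bogus", {})], seed=0)

    def test_composition_order_reported(self):
        rng = np.random.default_rng(6)
        dos = rng.integers(0, 3, size=(12, 60))
        G = tiny_matrix(dos)
        G.loci["pos"] = np.sort(rng.choice(10_000, 60, replace=False)) + 1
        steps = [
            ("thin_bp", {"min_bp": 50}),
            ("missingness", {"max_missing": 0.3}),
            ("hwe", {"alpha": 0.001}),
            ("ld_prune", {"r2_threshold": 0.8, "window_bp": 1000}),
        ]
        out, rep = apply_site_filters(G, steps, seed=1)
        assert [s.name for s in rep.steps] == [s[0] for s in steps]
        for s in rep.steps:
            assert s.n_out == s.n_in - s.n_removed
        assert rep.steps[-1].n_out == out.n_loci
        # determinism of the whole composed stack
        out2, _ = apply_site_filters(G, steps, seed=1)
        assert out.loci.equals(out2.loci)
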