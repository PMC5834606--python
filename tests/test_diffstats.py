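"""Weir-Cockerham theta, AMOVA phi_ST and diversity against oracles."""

import numpy as np
import pytest

from conftest import tiny_matrix
from fusionscan.diffstats import (
    StatError,
    allele_frequencies,
    diversity_stats,
    heterozygosity,
    nucleotide_diversity,
    phi_st,
    wc_fst,
)
from oracles import amova_phi_st, wc_theta_anova


class TestAlleleFrequencies:
    def test_diploid_counts(self):
        G = tiny_matrix([[1], [1]])
        tab = allele_frequencies(G, {"g": ["s0", "s1"]})
        assert tab.freq[0, 0] == pytest.approx(0.5)
        assert tab.n_alleles[0, 0] == 4

    def test_hemizygote_contributes_one_allele(self):
        G = tiny_matrix([[1], [0]], ploidy=[[1], [2]], z_linked=[True])
        tab = allele_frequencies(G, {"g": ["s0", "s1"]})
        assert tab.n_alleles[0, 0] == 3
        assert tab.freq[0, 0] == pytest.approx(1 / 3)

    def test_all_missing_locus_is_nan_with_zero_count(self):
        G = tiny_matrix([[-1], [-1]])
        tab = allele_frequencies(G, {"g": ["s0", "s1"]})
        assert np.isnan(tab.freq[0, 0]) and tab.n_alleles[0, 0] == 0

    def test_sample_in_two_groups_rejected(self):
        G = tiny_matrix([[0], [1]])
        with pytest.raises(StatError, match="both"):
            allele_frequencies(G, {"a": ["s0"], "b": ["s0", "s1"]})


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        dos = np.vstack([np.full((10, 1), 2), np.zeros((10, 1), dtype=int)])
        G = tiny_matrix(dos)
        res = wc_fst(G, [f"s{i}" for i in range(10)],
                     [f"s{i}" for i in range(10, 20)])
        assert res.theta[0] == pytest.approx(1.0)
        assert res.mean_theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(8, 20))
        G = tiny_matrix(np.vstack([block, block]))
        res = wc_fst(G, [f"s{i}" for i in range(8)],
                     [f"s{i}" for i in range(8, 16)])
        assert np.all(res.theta[np.isfinite(res.theta)] <= 1e-12)

    def test_textbook_counts_match_anova_oracle(self):
        dosA = np.repeat([0, 1, 2], [6, 3, 1])
        dosB = np.repeat([0, 1, 2], [1, 3, 6])
        G = tiny_matrix(np.concatenate([dosA, dosB])[:, None])
        res = wc_fst(G, [f"s{i}" for i in range(10)],
                     [f"s{i}" for i in range(10, 20)])
        a, b, c = wc_theta_anova(dosA, dosB)
        assert res.a[0] == pytest.approx(a, abs=1e-12)
        assert res.b[0] == pytest.approx(b, abs=1e-12)
        assert res.c[0] == pytest.approx(c, abs=1e-12)
        assert res.theta[0] == pytest.approx(a / (a + b + c), abs=1e-12)

    def test_random_instances_match_anova_oracle(self):
        """Component-formula theta == allele-indicator ANOVA theta, 1e-12."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(120):
            nA = rng.integers(2, 21)
            nB = rng.integers(2, 21)
            p = rng.uniform(0.05, 0.95, size=2)
            dosA = rng.binomial(2, p[0], size=nA)
            dosB = rng.binomial(2, p[1], size=nB)
            G = tiny_matrix(np.concatenate([dosA, dosB])[:, None])
            res = wc_fst(G, [f"s{i}" for i in range(nA)],
                         [f"s{i}" for i in range(nA, nA + nB)])
            a, b, c = wc_theta_anova(dosA, dosB)
            if a + b + c == 0:
                assert np.isnan(res.theta[0])
                continue
            assert res.theta[0] == pytest.approx(a / (a + b + c), abs=1e-12)
            checked += 1
        assert checked >= 100

    def test_hemizygous_calls_excluded(self):
        # one female haploid call should not perturb the diploid-only theta
        dos = np.array([[2], [2], [2], [0], [0], [0], [1]])
        plo = np.array([[2], [2], [2], [2], [2], [2], [1]])
        G = tiny_matrix(dos, ploidy=plo, z_linked=[True])
        with_hemi = wc_fst(G, ["s0", "s1", "s2", "s6"], ["s3", "s4", "s5"])
        without = wc_fst(G, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert with_hemi.theta[0] == pytest.approx(without.theta[0])

    def test_too_small_population_rejected(self):
        G = tiny_matrix([[0], [1], [2]])
        with pytest.raises(StatError):
            wc_fst(G, ["s0"], ["s1", "s2"])


class TestPhiSt:
    def test_fixed_haplotype_difference_gives_one(self):
        seqs = ["AAAA"] * 3 + ["AAAT"] * 3
        res = phi_st(seqs, ["x"] * 3 + ["y"] * 3, n_perm=50, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert 0 < res.p_value <= 1

    def test_identical_composition_nonpositive(self):
        seqs = ["AAAA", "AAAT", "AAAA", "AAAT"]
        res = phi_st(seqs, ["x", "x", "y", "y"], n_perm=50, seed=0)
        assert res.phi_st <= 1e-12

    def test_mixed_haplotypes_match_sums_of_squares_oracle(self):
        seqs = ["AAAA", "AAAT", "AATT", "AAAA", "TTTT", "TTTA", "TTAA", "TTTT"]
        labels = ["x"] * 4 + ["y"] * 4
        res = phi_st(seqs, labels, n_perm=20, seed=1)
        assert res.phi_st == pytest.approx(amova_phi_st(seqs, labels), abs=1e-12)

    def test_null_permutation_p_roughly_uniform(self):
        """Under shuffled labels the permutation p-value is ~uniform: its
        mean over replicates should be near 0.5."""
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        ps = []
        for rep in range(120):
            seqs = ["".join(rng.choice(bases, 12)) for _ in range(8)]
            res = phi_st(seqs, ["x"] * 4 + ["y"] * 4, n_perm=49, seed=rep)
            ps.append(res.p_value)
        assert 0.35 < np.mean(ps) < 0.65

    def test_single_sequence_group_rejected(self):
        with pytest.raises(StatError):
            phi_st(["AA", "AT", "TT"], ["x", "y", "y"], n_perm=10, seed=0)


class TestDiversity:
    def test_identical_haplotypes_zero_pi(self):
        assert nucleotide_diversity(["ACGT", "ACGT"]) == 0.0

    def test_hand_computed_pi(self):
        # 3 haplotypes of length 10 with pairwise differences {2, 2, 4}
        seqs = ["AAAAAAAAAA", "TTAAAAAAAA", "AATTAAAAAA"]
        assert nucleotide_diversity(seqs) == pytest.approx((2 + 2 + 4) / 3 / 10)

    def test_single_heterozygote_ho(self):
        G = tiny_matrix([[1], [1]])
        ho, he = heterozygosity(G, ["s0"])
        assert ho == pytest.approx(1.0)

    def test_he_is_2pq(self):
        G = tiny_matrix([[0], [1], [2], [1]])
        _, he = heterozygosity(G, [f"s{i}" for i in range(4)])
        assert he == pytest.approx(2 * 0.5 * 0.5)

    def test_table_contains_all_groups(self):
        G = tiny_matrix([[0], [1], [2], [1]])
        t = diversity_stats(G, {"a": ["s0", "s1"], "b": ["s2", "s3"]},
                            haplotypes={"s0": "AAAA", "s1": "AATA"})
        assert t["group"].tolist() == ["a", "b"]
        assert t.loc[0, "pi"] == pytest.approx(1 / 4)
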