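"""Diagnostic panels, SNP/genomic profiles, mtDNA assignment, uncoupling."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_matrix
from fusionscan import SimConfig, simulate_fusion_dataset
from fusionscan.profiles import (
    ProfileError,
    assign_mtdna,
    build_diagnostic_panel,
    discordance_flags,
    genomic_profile,
    mitonuclear_independence_test,
    profile_table,
    snp_profile,
    snp_profile_counts,
    z_layer_assignment,
)


def _two_pop_matrix():
    # 4 CAL (alt-fixed at locus 0), 4 HOL (ref-fixed at locus 0);
    # locus 1 strongly but not fully differentiated; locus 2 undifferentiated
    dos = np.array(
        [
            [2, 2, 1], [2, 2, 1], [2, 2, 1], [2, 1, 1],
            [0, 0, 1], [0, 0, 1], [0, 0, 1], [0, 1, 1],
        ]
    )
    G = tiny_matrix(dos)
    cal = [f"s{i}" for i in range(4)]
    hol = [f"s{i}" for i in range(4, 8)]
    return G, cal, hol


class TestPanel:
    def test_fixed_rule_selects_fixed_locus_with_orientation(self):
        G, cal, hol = _two_pop_matrix()
        panel = build_diagnostic_panel(G, cal, hol, rule="fixed")
        assert panel.loci["locus_index"].tolist() == [0]
        assert panel.loci["cal_allele"].tolist() == ["alt"]
        assert panel.loci["theta"].iloc[0] == pytest.approx(1.0)

    def test_fst_threshold_is_strict(self):
        G, cal, hol = _two_pop_matrix()
        theta1 = build_diagnostic_panel(G, cal, hol, rule="fst_gt",
                                        threshold=0.0).loci.set_index(
                                            "locus_index")["theta"]
        # excluding at exactly the locus's own theta must drop it
        t = float(theta1.loc[1])
        panel = build_diagnostic_panel(G, cal, hol, rule="fst_gt", threshold=t)
        assert 1 not in panel.loci["locus_index"].tolist()
        panel2 = build_diagnostic_panel(G, cal, hol, rule="fst_gt",
                                        threshold=t - 1e-9)
        assert 1 in panel2.loci["locus_index"].tolist()

    def test_identical_references_give_empty_panel(self):
        G = tiny_matrix(np.tile([[1], [1], [1], [1]], (2, 1)))
        panel = build_diagnostic_panel(
            G, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)],
            rule="fixed",
        )
        assert len(panel) == 0  # warning, not fatal

    def test_panel_deterministic_and_idempotent(self):
        G, cal, hol = _two_pop_matrix()
        a = build_diagnostic_panel(G, cal, hol, rule="fst_gt", threshold=0.2)
        b = build_diagnostic_panel(G, cal, hol, rule="fst_gt", threshold=0.2)
        pd.testing.assert_frame_equal(a.loci, b.loci)

    def test_overlapping_references_rejected(self):
        G, cal, hol = _two_pop_matrix()
        with pytest.raises(ProfileError, match="disjoint"):
            build_diagnostic_panel(G, cal, cal, rule="fixed")


class TestSnpProfile:
    def test_states_follow_orientation(self):
        G, cal, hol = _two_pop_matrix()
        panel = build_diagnostic_panel(G, cal, hol, rule="fixed")
        assert snp_profile(G, "s0", panel)["state"].tolist() == ["CC"]
        assert snp_profile(G, "s4", panel)["state"].tolist() == ["HH"]

    def test_f1_individuals_all_heterozygous_at_fixed_panel(self):
        cfg = SimConfig(n_loci=2000, n_pops=3, samples_per_pop=25, seed=14,
                        mode="recent_contact", missing_rate=0.0,
                        frac_resistant=0.0, cline_width_km=300.0)
        sim = simulate_fusion_dataset(cfg)
        meta = sim.metadata
        pure_cal = meta[(sim.truth["true_q_HOL"] == 0)]["sample"].tolist()
        pure_hol = meta[(sim.truth["true_q_HOL"] == 1)]["sample"].tolist()
        panel = build_diagnostic_panel(sim.genotypes, pure_cal, pure_hol,
                                       rule="fixed")
        auto = ~sim.genotypes.loci["z_linked"].to_numpy()[
            panel.loci["locus_index"]]
        f1s = sim.truth[sim.truth["is_f1"]]["sample"].tolist()
        assert len(panel) > 0 and len(f1s) > 0
        for s in f1s[:5]:
            states = snp_profile(sim.genotypes, s, panel)["state"].to_numpy()
            assert set(states[auto]) <= {"CH"}

    def test_long_admixed_individual_is_a_mosaic(self):
        """mode=fusion q~0.5 genomes mix CC, CH and HH panel states."""
        cfg = SimConfig(n_loci=1500, n_pops=3, samples_per_pop=25, seed=15,
                        missing_rate=0.0, cline_width_km=300.0,
                        frac_resistant=0.0)
        sim = simulate_fusion_dataset(cfg)
        pops = sim.metadata.groupby("population")["sample"].apply(list)
        panel = build_diagnostic_panel(sim.genotypes, pops["P01"], pops["P03"],
                                       rule="fst_gt", threshold=0.58)
        counts = snp_profile_counts(
            snp_profile(sim.genotypes, pops["P02"][0], panel)
        )
        assert counts["CC"] > 0 and counts["CH"] > 0 and counts["HH"] > 0

    def test_hemizygous_states_kept_separate(self):
        G = tiny_matrix([[2, 1], [2, 1], [0, 0], [0, 0]],
                        ploidy=[[2, 2], [2, 2], [2, 2], [2, 1]],
                        z_linked=[False, True])
        panel = build_diagnostic_panel(G, ["s0", "s1"], ["s2", "s3"],
                                       rule="fst_gt", threshold=0.2)
        states = snp_profile(G, "s3", panel)
        z_states = states[states["locus_index"] == 1]["state"]
        assert set(z_states) <= {"C", "H"}


class TestMtdnaAssignment:
    REFS = {"CAL": ["AAAA"], "HOL": ["TTTT"], "CHI": ["GGGG"]}

    def test_exact_match(self):
        assert assign_mtdna("AAAA", self.REFS) == "CAL"

    def test_one_private_mutation_still_assigned(self):
        assert assign_mtdna("TTTA", self.REFS) == "HOL"

    def test_equidistant_is_ambiguous(self):
        assert assign_mtdna("AATT", self.REFS) == "ambiguous"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ProfileError):
            assign_mtdna("AAA", self.REFS)


class TestGenomicProfile:
    def test_rule_application(self):
        row = genomic_profile("x", "HOL", "ADMIXED", [0.1, 0.9], [0.45, 0.55])
        assert (row["mt"], row["Z"], row["auto"], row["SNP"]) == (
            "HOL", "ADMIXED", "HOL", "ADMIXED")

    def test_z_heterozygote_always_admixed(self):
        G = tiny_matrix([[1]], z_linked=[True])
        assert z_layer_assignment(G, "s0", 0, "alt") == "ADMIXED"

    def test_fewer_than_three_layers_excluded(self):
        with pytest.raises(ProfileError, match="3"):
            genomic_profile("x", "HOL", None, None, [0.5, 0.5])

    def test_discordant_mt_flagged(self):
        """Pure CAL nuclear layers with HOL mtDNA: the mosaic signature."""
        rows = [
            genomic_profile("isl", "HOL", "CAL", [0.95, 0.05], [0.9, 0.1]),
            genomic_profile("conc", "CAL", "CAL", [0.95, 0.05], [0.9, 0.1]),
        ]
        flags = discordance_flags(profile_table(rows))
        assert flags.tolist() == [True, False]


class TestUncoupling:
    def test_constant_q_gives_p_one(self):
        res = mitonuclear_independence_test(
            ["CAL"] * 6 + ["HOL"] * 6, [0.5] * 12, n_perm=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_recent_contact_strongly_rejected(self):
        """mt class predicts nuclear q in an F1 swarm: p <= 0.01."""
        rng = np.random.default_rng(16)
        q = np.concatenate([np.zeros(15), np.ones(15), np.full(20, 0.5)])
        mt = ["CAL"] * 15 + ["HOL"] * 15 + [
            "HOL" if rng.random() < 0.5 else "CAL" for _ in range(20)]
        res = mitonuclear_independence_test(mt, q, n_perm=999, seed=1)
        assert res.p_value <= 0.01

    def test_single_mt_class_rejected(self):
        with pytest.raises(ProfileError):
            mitonuclear_independence_test(["CAL"] * 12, [0.5] * 12,
                                          n_perm=10, seed=0)

    def test_output_labels_itself_an_extension(self):
        res = mitonuclear_independence_test(
            ["CAL"] * 6 + ["HOL"] * 6, list(np.linspace(0, 1, 12)),
            n_perm=99, seed=0)
        assert "formalisation" in res.note

    def test_fusion_contact_zone_more_discordant_than_pure_regions(self):
        """Fraction of mt-vs-nuclear discordant assignments peaks in the
        admixed centre of a fusion-mode transect."""
        cfg = SimConfig(n_loci=800, n_pops=5, samples_per_pop=30, seed=17,
                        cline_width_km=400.0, missing_rate=0.0)
        sim = simulate_fusion_dataset(cfg)
        truth = sim.truth[sim.truth["distance_km"].notna()]
        nuclear = np.where(truth["true_q_HOL"] > 0.5, "HOL", "CAL")
        discord = (truth["true_mt_lineage"].to_numpy() != nuclear)
        center = truth["distance_km"].between(800, 1200).to_numpy()
        edge = (truth["distance_km"] < 400).to_numpy() | (
            truth["distance_km"] > 1600).to_numpy()
        assert discord[center].mean() > discord[edge].mean()
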