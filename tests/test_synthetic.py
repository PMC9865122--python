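"""Synthetic screen, interactome and gene-set generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abtox import (ScreenDesign, compute_growth_ratios, read_gmt,
                   simulate_genesets, simulate_interactome, simulate_screen,
                   write_gmt)
from abtox.synthetic import InvalidDesignError


class TestScreenDesign:
    def test_fraction_sum_over_one_rejected(self):
        with pytest.raises(InvalidDesignError):
            ScreenDesign(n_strains=100, enhancer_fraction=0.6,
                         protective_fraction=0.6)

    @pytest.mark.parametrize("kwargs", [
        {"noise_cv": -0.1},
        {"n_strains": 0},
        {"n_replicates": 0},
        {"enhancer_fraction": 1.5},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidDesignError):
            ScreenDesign(**kwargs)


class TestSimulateScreen:
    def test_same_seed_bitwise_identical(self, tmp_path):
        design = ScreenDesign(n_strains=96, enhancer_fraction=0.1,
                              noise_cv=0.2, rng_seed=7)
        t1, g1 = simulate_screen(design)
        t2, g2 = simulate_screen(design)
        pd.testing.assert_frame_equal(t1, t2)
        assert g1.to_json() == g2.to_json()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t1.to_csv(p1, sep="\t", index=False)
        t2.to_csv(p2, sep="\t", index=False)
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_noise_ratio_equals_multiplier(self):
        design = ScreenDesign(n_strains=10, noise_cv=0.0, rng_seed=0,
                              neutral_profile={3: 0.2, 4: 0.09, 5: 0.39})
        table, truth = simulate_screen(design)
        scores = compute_growth_ratios(table, tau=0.0)
        neutral = truth.strains_of_class("neutral")
        sub = scores.strains[scores.strains["strain"].isin(neutral)]
        assert sub["r4"].to_numpy() == pytest.approx(0.09, abs=1e-12)
        assert sub["r5"].to_numpy() == pytest.approx(0.39, abs=1e-12)

    def test_every_strain_has_one_class(self):
        design = ScreenDesign(n_strains=50, enhancer_fraction=0.2,
                              protective_fraction=0.2, rng_seed=3)
        table, truth = simulate_screen(design)
        strains = set(table["strain"])
        assert strains == set(truth.classes)
        valid = {"neutral", "enhancer_gene", "protective_gene",
                 "gal_deficient", "glu_deficient"}
        assert set(truth.classes.values()) <= valid

    def test_planted_enhancer_mean_ratio_near_rescue_level(self):
        design = ScreenDesign(n_strains=384, enhancer_fraction=0.05,
                              noise_cv=0.15, rng_seed=1)
        table, truth = simulate_screen(design)
        scores = compute_growth_ratios(table)
        enh = truth.strains_of_class("enhancer_gene")
        sub = scores.strains[scores.strains["strain"].isin(enh)]
        assert len(sub) == len(enh) > 0
        assert abs(sub["r4"].mean() - design.rescue_level) < 0.05

    def test_protective_strains_below_detection_floor(self, noisy_screen):
        design, table, truth = noisy_screen
        prot = set(truth.strains_of_class("protective_gene"))
        gal = table[(table["condition"] == "GAL")
                    & table["strain"].isin(prot)]
        assert (gal["size"] < design.detection_floor).all()

    def test_glu_deficient_strains_small_on_glucose(self, noisy_screen):
        design, table, truth = noisy_screen
        glu_def = set(truth.strains_of_class("glu_deficient"))
        glu = table[(table["condition"] == "GLU")
                    & table["strain"].isin(glu_def)]
        assert (glu["size"] < 0.1 * design.base_size).all()

    def test_truth_json_round_trip(self, noisy_screen):
        _, _, truth = noisy_screen
        restored = type(truth).from_json(truth.to_json())
        assert restored.classes == truth.classes
        assert restored.induced_multipliers == truth.induced_multipliers
        assert restored.control_strains == truth.control_strains


class TestSimulateInteractome:
    def test_full_density_module_is_clique(self):
        edges, truth = simulate_interactome(30, 0.05, [(8, 1.0)], seed=0)
        members = set(truth["modules"][0])
        internal = edges[edges["protein1"].isin(members)
                         & edges["protein2"].isin(members)]
        assert len(internal) == 8 * 7 // 2

    def test_zero_background_confines_edges_to_module(self):
        edges, truth = simulate_interactome(50, 0.0, [(6, 0.9)], seed=1)
        members = set(truth["modules"][0])
        assert edges["protein1"].isin(members).all()
        assert edges["protein2"].isin(members).all()

    def test_edge_count_within_3_sigma_of_binomial(self):
        n, p = 100, 0.03
        edges, truth = simulate_interactome(n, p, [(8, 1.0)], seed=3)
        planted_pairs = 8 * 7 // 2
        background_pairs = n * (n - 1) // 2 - planted_pairs
        expected = background_pairs * p + planted_pairs
        sigma = np.sqrt(background_pairs * p * (1 - p))
        assert abs(len(edges) - expected) <= 3 * sigma

    def test_planted_edges_survive_confidence_filter(self):
        edges, truth = simulate_interactome(40, 0.05, [(8, 1.0)], seed=2)
        members = set(truth["modules"][0])
        internal = edges[edges["protein1"].isin(members)
                         & edges["protein2"].isin(members)]
        assert (internal["combined_score"] >= 400).all()

    def test_density_not_exceeding_background_rejected(self):
        with pytest.raises(ValueError):
            simulate_interactome(20, 0.5, [(5, 0.4)], seed=0)

    def test_module_larger_than_graph_rejected(self):
        with pytest.raises(ValueError):
            simulate_interactome(5, 0.1, [(10, 1.0)], seed=0)

    def test_same_seed_identical_tables(self):
        e1, _ = simulate_interactome(60, 0.05, [(6, 0.9)], seed=9)
        e2, _ = simulate_interactome(60, 0.05, [(6, 0.9)], seed=9)
        pd.testing.assert_frame_equal(e1, e2)


class TestSimulateGenesets:
    GENES = [f"G{i:04d}" for i in range(1, 1001)]

    def test_empty_enriched_set_gives_only_random_sets(self):
        sets = simulate_genesets(self.GENES, 10, seed=0)
        assert len(sets) == 10
        assert "PLANTED_SET" not in sets

    def test_designated_set_contains_enriched_genes(self):
        enriched = self.GENES[:10]
        sets = simulate_genesets(self.GENES, 20, enriched_set=enriched,
                                 seed=4)
        assert set(enriched) <= set(sets["PLANTED_SET"])

    def test_gmt_round_trip_preserves_membership(self, tmp_path):
        sets = simulate_genesets(self.GENES, 15,
                                 enriched_set=self.GENES[:8], seed=5)
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        assert read_gmt(path) == sets

    def test_planted_set_highly_significant(self):
        # 10/10 query genes inside the designated set against N=1000
        enriched = self.GENES[:10]
        sets = simulate_genesets(self.GENES, 50, enriched_set=enriched,
                                 seed=6)
        K = len(sets["PLANTED_SET"])
        p = stats.hypergeom.sf(9, 1000, K, 10)
        assert p < 1e-6

    def test_enriched_genes_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            simulate_genesets(self.GENES[:50], 5, enriched_set=["NOPE"],
                              seed=0)
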