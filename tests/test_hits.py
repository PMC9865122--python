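"""Hit calling: confounder filters, threshold rules, volcano statistic."""

import numpy as np
import pandas as pd
import pytest

from abtox import (HitThresholds, ScreenDesign, apply_confounder_filters,
                   call_hits, compute_growth_ratios, run_hit_calling,
                   simulate_screen, volcano_statistics)
from oracles import bh_adjust


def strain_row(strain, r4, r5, zero_d5=False, glu_def=False, plate=1):
    return {"strain": strain, "plate": plate, "n_replicates": 2,
            "glu_deficient_observed": glu_def, "r3": 0.0, "zero_d3": False,
            "r4": r4, "zero_d4": False, "r5": r5, "zero_d5": zero_d5}


class TestConfounderFilters:
    def test_nothing_to_exclude(self):
        strains = pd.DataFrame([strain_row("S1", 0.1, 0.4)])
        retained, exclusions = apply_confounder_filters(strains, [])
        assert len(retained) == 1
        assert exclusions.empty

    def test_known_gal_deficient_excluded(self):
        strains = pd.DataFrame([strain_row("S1", 0.1, 0.4),
                                strain_row("S2", 0.1, 0.4)])
        retained, exclusions = apply_confounder_filters(strains, ["S2"])
        assert list(retained["strain"]) == ["S1"]
        assert exclusions.iloc[0].tolist() == ["S2", "gal_deficient_known"]

    def test_observed_glu_deficiency_excluded(self):
        strains = pd.DataFrame([strain_row("S1", np.nan, np.nan,
                                           glu_def=True)])
        _, exclusions = apply_confounder_filters(strains, [])
        assert exclusions.iloc[0]["reason"] == "glu_deficient_observed"

    def test_planted_glu_deficient_strains_all_excluded(self, noisy_screen,
                                                        noisy_scores):
        _, _, truth = noisy_screen
        _, exclusions = apply_confounder_filters(
            noisy_scores.strains, truth.known_gal_deficient)
        excluded = set(exclusions["strain"])
        for strain in truth.strains_of_class("glu_deficient"):
            assert strain in excluded
        for strain in truth.strains_of_class("gal_deficient"):
            assert strain in excluded


class TestCallHits:
    def test_control_profile_is_no_call(self):
        strains = pd.DataFrame([strain_row("CTRL", 0.09, 0.39)])
        assert call_hits(strains)["call"].iloc[0] == "no_call"

    def test_rescue_threshold_inclusive_at_exactly_0_7(self):
        strains = pd.DataFrame([strain_row("S1", 0.7, 0.8)])
        assert call_hits(strains)["call"].iloc[0] == "enhancer_gene"

    def test_just_below_threshold_is_not_enhancer(self):
        strains = pd.DataFrame([strain_row("S1", 0.699999, 0.8)])
        assert call_hits(strains)["call"].iloc[0] == "no_call"

    def test_all_replicate_zero_at_day5_is_protective(self):
        strains = pd.DataFrame([strain_row("S1", 0.0, 0.0, zero_d5=True)])
        assert call_hits(strains)["call"].iloc[0] == "protective_gene"

    def test_raising_threshold_never_adds_enhancers(self):
        rng = np.random.default_rng(5)
        strains = pd.DataFrame([strain_row(f"S{i}", rng.uniform(0, 1.2),
                                           rng.uniform(0, 1.2))
                                for i in range(50)])
        previous = None
        for theta in (0.5, 0.7, 0.9, 1.1):
            calls = call_hits(strains, HitThresholds(rescue_threshold=theta))
            enh = set(calls[calls["call"] == "enhancer_gene"]["strain"])
            if previous is not None:
                assert enh <= previous
            previous = enh

    def test_equal_rescue_and_zero_day_rejected(self):
        with pytest.raises(ValueError):
            HitThresholds(rescue_day=5, zero_day=5)


class TestVolcanoStatistics:
    def make_scores(self):
        rows = [strain_row(f"C{i}", 0.09 + 0.001 * i, 0.4)
                for i in range(4)]
        rows += [strain_row(f"S{i}", r4, 0.4)
                 for i, r4 in enumerate([0.9, 0.85, 0.1, 0.11, 0.09, 0.12,
                                         0.08, 0.13])]
        return pd.DataFrame(rows)

    def test_strain_equal_to_control_has_null_statistics(self):
        strains = self.make_scores()
        out = volcano_statistics(strains, [f"C{i}" for i in range(4)])
        ctrl_mean = np.mean([0.09 + 0.001 * i for i in range(4)])
        near = out[out["strain"] == "S4"].iloc[0]  # r4 = 0.09 ≈ control
        assert abs(near["log2fc"]) < 0.05
        assert near["p"] > 0.5

    def test_rescued_strains_get_large_positive_fold_change(self):
        strains = self.make_scores()
        out = volcano_statistics(strains, [f"C{i}" for i in range(4)])
        strong = out.set_index("strain").loc["S0"]
        assert strong["log2fc"] > 3.0
        assert strong["p"] < 0.01

    def test_q_values_match_bh_oracle(self):
        strains = self.make_scores()
        out = volcano_statistics(strains, [f"C{i}" for i in range(4)])
        expected = bh_adjust(list(out["p"]))
        assert out["q"].to_numpy() == pytest.approx(expected, rel=1e-12)

    def test_bh_oracle_hand_case(self):
        # classic worked example: p = .01,.02,.03,.04 -> q all .04
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_q_at_least_p_and_bounded(self):
        strains = self.make_scores()
        out = volcano_statistics(strains, [f"C{i}" for i in range(4)])
        ok = np.isfinite(out["p"])
        assert (out.loc[ok, "q"] >= out.loc[ok, "p"] - 1e-15).all()
        assert (out.loc[ok, "q"] <= 1.0).all()

    def test_missing_controls_rejected(self):
        strains = self.make_scores()
        with pytest.raises(ValueError):
            volcano_statistics(strains, ["NOT_THERE"])


class TestRunHitCalling:
    def test_partition_into_exactly_one_call(self, noisy_screen,
                                             noisy_scores):
        _, _, truth = noisy_screen
        calls = run_hit_calling(noisy_scores, truth.known_gal_deficient,
                                control_strains=truth.control_strains)
        assert calls["strain"].is_unique
        scored = set(noisy_scores.strains["strain"]) | set(
            noisy_scores.warnings["strain"])
        assert set(calls["strain"]) == scored
        assert set(calls["call"]) <= {"enhancer_gene", "protective_gene",
                                      "no_call", "excluded"}

    def test_excluded_rows_carry_reason_codes(self, noisy_screen,
                                              noisy_scores):
        _, _, truth = noisy_screen
        calls = run_hit_calling(noisy_scores, truth.known_gal_deficient,
                                control_strains=truth.control_strains)
        excluded = calls[calls["call"] == "excluded"]
        assert (excluded["reasons"].str.len() > 0).all()

    def test_zero_noise_calls_match_truth_perfectly(self, zero_noise_screen):
        _, measurements, truth = zero_noise_screen
        scores = compute_growth_ratios(measurements)
        calls = run_hit_calling(scores, truth.known_gal_deficient,
                                control_strains=truth.control_strains)
        by_strain = calls.set_index("strain")["call"]
        for strain, cls in truth.classes.items():
            if strain in truth.control_strains:
                continue
            if cls in ("enhancer_gene", "protective_gene"):
                assert by_strain[strain] == cls
            elif cls == "neutral":
                assert by_strain[strain] == "no_call"
            else:
                assert by_strain[strain] == "excluded"

    def test_noisy_recovery_is_accurate(self, noisy_screen, noisy_scores):
        _, _, truth = noisy_screen
        calls = run_hit_calling(noisy_scores, truth.known_gal_deficient,
                                control_strains=truth.control_strains)
        by_strain = calls.set_index("strain")["call"]
        for cls in ("enhancer_gene", "protective_gene"):
            planted = truth.strains_of_class(cls)
            recovered = sum(by_strain[s] == cls for s in planted)
            assert recovered / len(planted) >= 0.85
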