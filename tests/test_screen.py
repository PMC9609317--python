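"""Nontargeted screening: matching, percent remaining, detection, balance."""

import numpy as np
import pandas as pd
import pytest

from mixtox import (
    ClosureWarning,
    detect_metabolites,
    mass_balance,
    match_features,
    percent_remaining,
    percent_remaining_table,
)


def feature_frame(rows):
    """rows: (mz, ccs, abundance[, time, condition, replicate])."""
    full = []
    for i, row in enumerate(rows):
        mz, ccs, ab = row[:3]
        t = row[3] if len(row) > 3 else 0.0
        cond = row[4] if len(row) > 4 else "treated"
        rep = row[5] if len(row) > 5 else 1
        full.append((f"s_{cond}_r{rep}", cond, rep, t, mz, ccs, 0.1 * ccs, ab))
    return pd.DataFrame(
        full,
        columns=["sample_id", "condition", "replicate", "time_min", "mz", "ccs", "drift_time_ms", "abundance"],
    )


class TestMatchFeatures:
    def test_within_both_windows_matches(self, library):
        # near the 2,4-dinitrophenol library values (183.01, 127.81)
        out = match_features(feature_frame([(183.006, 127.5, 1e4)]), library)
        assert out["compound"].iloc[0] == "2,4-Dinitrophenol"
        assert abs(out["mz_error"].iloc[0]) <= 0.02
        assert abs(out["ccs_error_pct"].iloc[0]) <= 1.0

    def test_mz_out_of_window_unmatched(self, library):
        out = match_features(feature_frame([(184.01, 127.81, 1e4)]), library)
        assert out["compound"].iloc[0] == "unknown"

    def test_ccs_vetoes_good_mz(self, library):
        out = match_features(feature_frame([(183.01, 140.0, 1e4)]), library)
        assert out["compound"].iloc[0] == "unknown"

    def test_best_score_wins_between_isomers(self, library):
        # the two aminonitrophenols share m/z 153.03; CCS decides
        out = match_features(feature_frame([(153.03, 116.6, 1e4), (153.03, 117.8, 1e4)]), library)
        assert list(out["compound"]) == ["2-Amino-4-nitrophenol", "4-Amino-2-nitrophenol"]

    def test_tolerance_monotone(self, library, scenario, suspension_timecourse):
        from mixtox import simulate_feature_table

        ft = simulate_feature_table(
            suspension_timecourse, library, scenario.metabolite_yields, seed=21
        )
        narrow = match_features(ft, library, mz_tol=0.015, ccs_tol_pct=0.75)
        wide = match_features(ft, library, mz_tol=0.03, ccs_tol_pct=1.5)
        matched_narrow = narrow["compound"] != "unknown"
        matched_wide = wide["compound"] != "unknown"
        assert (matched_wide | ~matched_narrow).all()  # no match lost by widening

    def test_empty_library_rejected(self):
        from mixtox.chem import CompoundRecord, ReferenceLibrary

        # a valid library whose entries all lack IMS-MS values
        bare = ReferenceLibrary(
            [CompoundRecord(name="Lindane", casrn="58-89-9", role="parent", formula={"C": 6, "H": 6, "Cl": 6})]
        )
        with pytest.raises(ValueError, match="library"):
            match_features(feature_frame([(183.01, 127.81, 1e4)]), bare)

    def test_bad_tolerances_rejected(self, library):
        with pytest.raises(ValueError):
            match_features(feature_frame([(183.01, 127.81, 1e4)]), library, mz_tol=0.0)


class TestPercentRemaining:
    @pytest.mark.parametrize("treated,control,expected", [(5.0, 5.0, 100.0), (0.0, 5.0, 0.0), (2.5, 5.0, 50.0)])
    def test_ratios(self, treated, control, expected):
        assert percent_remaining(treated, control) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_remaining(1.0, 0.0)

    def test_table_flags_above_100_and_self_is_100(self, library):
        rows = [
            (183.008, 127.81, 900.0, 240.0, "treated", 1),
            (183.012, 127.81, 1000.0, 240.0, "control", 1),
            (371.912, 172.35, 1500.0, 240.0, "treated", 1),
            (371.909, 172.35, 1000.0, 240.0, "control", 1),
        ]
        assignments = match_features(feature_frame(rows), library)
        table = percent_remaining_table(assignments).set_index("compound")
        assert table.loc["2,4-Dinitrophenol", "percent_remaining"] == pytest.approx(90.0)
        assert not table.loc["2,4-Dinitrophenol", "above_100"]
        assert table.loc["Chlorpyrifos", "percent_remaining"] == pytest.approx(150.0)
        assert bool(table.loc["Chlorpyrifos", "above_100"])

    def test_control_against_itself_is_100(self, library, scenario, suspension_timecourse):
        from mixtox import simulate_feature_table

        ft = simulate_feature_table(
            suspension_timecourse, library, scenario.metabolite_yields, seed=33
        )
        assignments = match_features(ft, library)
        control_only = assignments[assignments["condition"] == "control"].copy()
        mirrored = pd.concat(
            [control_only, control_only.assign(condition="treated")], ignore_index=True
        )
        table = percent_remaining_table(mirrored)
        assert np.allclose(table["percent_remaining"], 100.0)


class TestReplicateMeanAbundance:
    def test_unmatched_replicate_counts_as_zero(self, library):
        from mixtox import replicate_mean_abundance

        # 2,4-DNP matched in replicates 1 and 2 only, out of 3 treated reps
        rows = [
            (183.01, 127.81, 300.0, 240.0, "treated", 1),
            (183.01, 127.81, 600.0, 240.0, "treated", 2),
            (371.91, 172.35, 100.0, 240.0, "treated", 3),
        ]
        assignments = match_features(feature_frame(rows), library)
        mean_ab = replicate_mean_abundance(assignments)
        assert mean_ab[("2,4-Dinitrophenol", "treated")] == pytest.approx(900.0 / 3)

    def test_identity_swap_within_parent_conserves_totals(self, library):
        from mixtox import replicate_mean_abundance

        # the same total aminonitrophenol signal, once under each isomer name:
        # the per-parent metabolite sum is unchanged
        swap = [
            (153.03, 116.54, 500.0, 240.0, "treated", 1),  # 2-amino-4-nitrophenol
            (153.03, 117.87, 500.0, 240.0, "treated", 2),  # 4-amino-2-nitrophenol
        ]
        mean_ab = replicate_mean_abundance(match_features(feature_frame(swap), library))
        total = sum(
            mean_ab.get((met, "treated"), 0.0)
            for met in library.metabolites_of("2,4-Dinitrophenol")
        )
        assert total == pytest.approx(1000.0 / 2)


class TestDetectMetabolites:
    def build_assignments(self, library, abundances_by_time, compound="2-Amino-4-nitrophenol"):
        entry = library.get(compound)
        rows = [
            (entry.library_mz, entry.library_ccs, ab, t, "treated", 1)
            for t, ab in abundances_by_time.items()
        ]
        return match_features(feature_frame(rows), library)

    def test_increasing_metabolite_detected_with_parents(self, library):
        assignments = self.build_assignments(library, {0.0: 50.0, 60.0: 200.0, 240.0: 900.0})
        out = detect_metabolites(assignments, library, min_abundance=100.0)
        assert list(out["metabolite"]) == ["2-Amino-4-nitrophenol"]
        row = out.iloc[0]
        assert row["parents"] == "2,4-Dinitrophenol"
        assert row["first_detection_time_min"] == 60.0

    def test_peak_before_final_time_excluded_when_increase_required(self, library):
        assignments = self.build_assignments(library, {0.0: 50.0, 60.0: 900.0, 240.0: 200.0})
        strict = detect_metabolites(assignments, library, require_increase=True)
        lax = detect_metabolites(assignments, library, require_increase=False)
        assert strict.empty
        assert list(lax["metabolite"]) == ["2-Amino-4-nitrophenol"]

    def test_below_threshold_not_detected(self, library):
        assignments = self.build_assignments(library, {0.0: 1.0, 240.0: 5.0})
        assert detect_metabolites(assignments, library, min_abundance=10.0).empty

    def test_single_timepoint_rejected(self, library):
        assignments = self.build_assignments(library, {240.0: 500.0})
        with pytest.raises(ValueError, match="timepoints"):
            detect_metabolites(assignments, library)

    def test_synthetic_run_detects_configured_metabolites(self, library, scenario, suspension_timecourse):
        from mixtox import simulate_feature_table

        ft = simulate_feature_table(
            suspension_timecourse, library, scenario.metabolite_yields, seed=13
        )
        assignments = match_features(ft, library)
        detected = set(detect_metabolites(assignments, library)["metabolite"])
        assert "2-Amino-4-nitrophenol" in detected
        assert "Diethylthiophosphate" in detected


class TestMassBalance:
    def test_closure_single_metabolite(self, library):
        r = mass_balance("2,4-Dinitrophenol", 40.0, {"2-Amino-4-nitrophenol": 35.0}, 100.0, library)
        assert r.parent_pct == pytest.approx(40.0)
        assert r.metabolite_pct["2-Amino-4-nitrophenol"] == pytest.approx(35.0)
        assert r.other_pct == pytest.approx(25.0)
        assert r.total_pct == pytest.approx(100.0, abs=1e-9)

    def test_no_metabolites_full_parent(self, library):
        r = mass_balance("Chlorpyrifos", 100.0, {}, 100.0, library)
        assert r.parent_pct == pytest.approx(100.0)
        assert r.other_pct == pytest.approx(0.0)

    def test_equal_split_divides_among_three_parents(self, library):
        r = mass_balance("Chlorpyrifos", 30.0, {"Diethylthiophosphate": 30.0}, 100.0, library)
        assert r.metabolite_pct["Diethylthiophosphate"] == pytest.approx(10.0)  # one third

    def test_full_to_each_does_not_split(self, library):
        r = mass_balance(
            "Chlorpyrifos", 30.0, {"Diethylthiophosphate": 30.0}, 100.0, library, rule="full_to_each"
        )
        assert r.metabolite_pct["Diethylthiophosphate"] == pytest.approx(30.0)

    def test_joint_rule_reports_multi_parent_separately(self, library):
        r = mass_balance(
            "Ethion",
            20.0,
            {"Diethylthiophosphate": 30.0, "Diethyldithiophosphate": 10.0},
            100.0,
            library,
            rule="joint",
        )
        assert "Diethylthiophosphate" not in r.metabolite_pct
        assert r.joint_unattributed["Diethylthiophosphate"] == pytest.approx(30.0)
        assert r.metabolite_pct["Diethyldithiophosphate"] == pytest.approx(10.0)
        assert r.total_pct == pytest.approx(100.0, abs=1e-9)

    def test_overshoot_floors_other_with_warning(self, library):
        with pytest.warns(ClosureWarning):
            r = mass_balance("2,4-Dinitrophenol", 90.0, {"2-Amino-4-nitrophenol": 30.0}, 100.0, library)
        assert r.other_pct == 0.0
        assert r.floored

    def test_foreign_metabolite_rejected(self, library):
        with pytest.raises(ValueError, match="not a registered metabolite"):
            mass_balance("Chlorpyrifos", 50.0, {"Disulfoton sulfone": 10.0}, 100.0, library)

    def test_bad_inputs_rejected(self, library):
        with pytest.raises(ValueError):
            mass_balance("Chlorpyrifos", 50.0, {}, 0.0, library)
        with pytest.raises(ValueError, match="rule"):
            mass_balance("Chlorpyrifos", 50.0, {}, 100.0, library, rule="halved")
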