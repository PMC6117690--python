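"""The three-step screen: thresholds, quantile filters, stability, audit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fucoscreen as fs
from fucoscreen.screening import ScreenConfig, chla_threshold, nilered_threshold

from conftest import brute_force_stage2, make_campaign


def plate_rows(sid, od, chla, nr, n_rep=3):
    return pd.DataFrame(
        {
            "strain_id": [sid] * n_rep,
            "replicate": range(1, n_rep + 1),
            "od625": [od] * n_rep,
            "rfu_chla": [chla] * n_rep,
            "rfu_nilered": [nr] * n_rep,
        }
    )


class TestFluorescenceFilter:
    def test_thresholds_at_od_010(self):
        assert chla_threshold(0.10) == pytest.approx(206.6)
        assert nilered_threshold(0.10) == pytest.approx(16.5, abs=1e-9)

    @pytest.mark.parametrize(
        "chla, nr, expect_pass, failing_rule",
        [
            (250.0, 20.0, True, None),
            (200.0, 20.0, False, "chla_pass"),
            (250.0, 10.0, False, "nr_pass"),
        ],
    )
    def test_examples_at_od_010(self, chla, nr, expect_pass, failing_rule):
        out = fs.fluorescence_filter(plate_rows("S1", 0.10, chla, nr))
        assert bool(out["passed"].iloc[0]) is expect_pass
        if failing_rule:
            assert not out[failing_rule].iloc[0]

    def test_boundary_equality_is_inclusive(self):
        # single replicate so the mean is bitwise equal to the threshold
        od = 0.10
        out = fs.fluorescence_filter(
            plate_rows("S1", od, chla_threshold(od), nilered_threshold(od), n_rep=1)
        )
        assert out["passed"].iloc[0]

    def test_replicates_averaged_before_thresholding(self):
        # individual replicates straddle the threshold; the mean passes
        od = 0.10
        thr = chla_threshold(od)
        plate = pd.DataFrame(
            {
                "strain_id": ["S1"] * 3,
                "replicate": [1, 2, 3],
                "od625": [od] * 3,
                "rfu_chla": [thr - 30, thr + 16, thr + 16],
                "rfu_nilered": [50.0] * 3,
            }
        )
        assert fs.fluorescence_filter(plate)["passed"].iloc[0]

    def test_non_positive_od_rows_rejected_with_warning(self):
        plate = pd.concat(
            [plate_rows("S1", 0.10, 250.0, 20.0), plate_rows("S2", -0.1, 250.0, 20.0)]
        )
        with pytest.warns(UserWarning, match="non-positive OD"):
            out = fs.fluorescence_filter(plate)
        assert list(out["strain_id"]) == ["S1"]

    def test_na_fluorescence_excluded_from_mean_with_warning(self):
        plate = plate_rows("S1", 0.10, 250.0, 20.0)
        plate.loc[0, "rfu_chla"] = np.nan
        with pytest.warns(UserWarning, match="NA fluorescence"):
            out = fs.fluorescence_filter(plate)
        assert out["rfu_chla"].iloc[0] == pytest.approx(250.0)

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            fs.fluorescence_filter(plate_rows("S1", 0.1, 250.0, 20.0).drop(columns="rfu_nilered"))

    def test_matches_brute_force_oracle_on_random_wells(self):
        rng = np.random.default_rng(123)
        n = 1000
        plate = pd.DataFrame(
            {
                "strain_id": [f"S{i:04d}" for i in range(n) for _ in range(3)],
                "replicate": [r for _ in range(n) for r in (1, 2, 3)],
                "od625": rng.uniform(0.05, 0.4, 3 * n),
                "rfu_chla": rng.uniform(0, 900, 3 * n),
                "rfu_nilered": rng.uniform(0, 70, 3 * n),
            }
        )
        out = fs.fluorescence_filter(plate)
        assert set(out.loc[out["passed"], "strain_id"]) == brute_force_stage2(plate)

    @given(bump=st.floats(0.0, 500.0), od=st.floats(0.05, 0.5))
    def test_monotone_in_fluorescence(self, bump, od):
        """Raising either channel can never flip a pass into a fail."""
        base = fs.fluorescence_filter(plate_rows("S1", od, 300.0, 30.0))
        bumped = fs.fluorescence_filter(plate_rows("S1", od, 300.0 + bump, 30.0 + bump))
        if base["passed"].iloc[0]:
            assert bumped["passed"].iloc[0]


class TestColonySelect:
    def test_identical_colonies_all_pass_at_zero_quantile(self):
        df = pd.DataFrame(
            {"strain_id": ["A", "B", "C"], "size": [1.0] * 3, "color_intensity": [2.0] * 3}
        )
        assert fs.colony_select(df, 0.0, 0.0) == ["A", "B", "C"]
        # ties are inclusive, so even extreme quantiles keep all of them
        assert fs.colony_select(df, 1.0, 1.0) == ["A", "B", "C"]

    def test_quantile_one_keeps_only_maxima(self):
        df = pd.DataFrame(
            {
                "strain_id": ["A", "B", "C"],
                "size": [1.0, 2.0, 3.0],
                "color_intensity": [5.0, 4.0, 6.0],
            }
        )
        assert fs.colony_select(df, 1.0, 1.0) == ["C"]

    def test_matches_brute_force_double_quantile_filter(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "strain_id": [f"S{i}" for i in range(300)],
                "size": rng.lognormal(0, 0.3, 300),
                "color_intensity": rng.lognormal(1, 0.2, 300),
            }
        )
        got = fs.colony_select(df, 0.8, 0.8)
        s_thr = np.quantile(df["size"], 0.8)
        c_thr = np.quantile(df["color_intensity"], 0.8)
        expected = sorted(
            df.loc[(df["size"] >= s_thr) & (df["color_intensity"] >= c_thr), "strain_id"]
        )
        assert got == expected

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fs.colony_select(pd.DataFrame(columns=["strain_id", "size", "color_intensity"]))


class TestCarotenoidFilter:
    def test_15pct_rule(self):
        profiles = {"A": 11.9, "B": 11.8, "C": 10.3}
        assert fs.carotenoid_filter(profiles, wt_car=10.3) == ["A"]  # threshold 11.845

    def test_raising_min_increase_never_enlarges_selection(self):
        rng = np.random.default_rng(11)
        profiles = {f"S{i}": float(v) for i, v in enumerate(rng.uniform(8, 16, 200))}
        prev = None
        for pct in (0.0, 5.0, 10.0, 15.0, 25.0, 50.0):
            sel = set(fs.carotenoid_filter(profiles, 10.3, pct))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_missing_wt_rejected(self):
        with pytest.raises(ValueError):
            fs.carotenoid_filter({"A": 12.0}, wt_car=0.0)


class TestStabilityAssess:
    def test_reverted_trajectory(self):
        status, reverted = fs.stability_assess(13.3, 10.2, wt_car=10.3)
        assert status == "unstable" and reverted

    @pytest.mark.parametrize("initial, final", [(10.0, 10.5), (12.0, 12.0), (10.0, 9.1)])
    def test_small_changes_are_stable(self, initial, final):
        status, _ = fs.stability_assess(initial, final)
        assert status == "stable"

    def test_non_positive_initial_rejected(self):
        with pytest.raises(ValueError):
            fs.stability_assess(0.0, 1.0)


class TestRunScreen:
    def test_planted_positives_always_selected(self, campaign):
        report = fs.run_screen(
            population=campaign["population"],
            plates=campaign["plates"],
            profiles=campaign["profiles"],
            colonies=campaign["colonies"],
            stability=campaign["stability"],
        )
        assert set(campaign["planted"]) <= set(report.selected)
        # no planted strain was dropped at any stage
        for stage in report.stages:
            assert not set(campaign["planted"]) & set(stage.dropped)

    def test_stage_survivors_are_nested_and_counts_match(self, campaign):
        report = fs.run_screen(
            population=campaign["population"],
            plates=campaign["plates"],
            profiles=campaign["profiles"],
            colonies=campaign["colonies"],
            stability=campaign["stability"],
        )
        prev = None
        for stage in report.stages:
            survivors = set(stage.survivors)
            assert stage.n_out == len(survivors)
            assert stage.n_in - stage.n_out == len(stage.dropped)
            if prev is not None:
                assert survivors <= prev
                assert stage.n_in == len(prev)
            prev = survivors
        assert set(report.selected) == prev

    def test_report_is_json_serialisable(self, campaign):
        import json

        report = fs.run_screen(
            population=campaign["population"],
            plates=campaign["plates"],
            profiles=campaign["profiles"],
        )
        json.dumps(report.to_dict())

    def test_empty_population(self, campaign):
        report = fs.run_screen(
            population=["WT"],
            plates=campaign["plates"],
            profiles=campaign["profiles"],
        )
        assert report.selected == []
        assert report.stages[0].n_in == 0

    def test_orphan_ids_rejected_with_listing(self, campaign):
        with pytest.raises(ValueError, match="GHOST"):
            fs.run_screen(
                population=campaign["population"] + ["GHOST"],
                plates=campaign["plates"],
                profiles=campaign["profiles"],
            )

    def test_wt_baseline_from_profiles(self, campaign):
        # omitting wt_car uses the WT profile entry; removing both errors
        profiles = {k: v for k, v in campaign["profiles"].items() if k != "WT"}
        with pytest.raises(ValueError, match="WT"):
            fs.run_screen(
                population=[s for s in campaign["population"] if s != "WT"],
                plates=campaign["plates"],
                profiles=profiles,
            )

    def test_stricter_quantiles_cannot_add_survivors(self):
        camp = make_campaign(n_strains=100, seed=9)
        loose = fs.run_screen(
            population=camp["population"],
            plates=camp["plates"],
            profiles=camp["profiles"],
            colonies=camp["colonies"],
            config=ScreenConfig(size_quantile=0.5, color_quantile=0.5),
        )
        strict = fs.run_screen(
            population=camp["population"],
            plates=camp["plates"],
            profiles=camp["profiles"],
            colonies=camp["colonies"],
            config=ScreenConfig(size_quantile=0.9, color_quantile=0.9),
        )
        assert set(strict.selected) <= set(loose.selected)
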