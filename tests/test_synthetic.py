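"""Generator behaviour: determinism, survivorship, calibration recovery,
absorbance inversion, dose-response, stability trajectories."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import fucoscreen as fs
from fucoscreen.synthetic import MUTAGEN_DOSE_TABLE


class TestGeneratePopulation:
    def test_deterministic_given_seed(self, gen_config):
        a = fs.generate_population(gen_config)
        b = fs.generate_population(gen_config)
        assert a == b

    def test_wt_reference_always_first(self, population, gen_config):
        wt = population[0]
        assert wt.strain_id == "WT" and wt.lineage == "WT" and wt.stable
        assert wt.true_car == gen_config.wt_car

    def test_zero_lethality_all_survive(self):
        cfg = fs.GeneratorConfig(n_strains=50, lethality=0.0, seed=1)
        pop = fs.generate_population(cfg)
        assert len(pop) == 51  # 50 mutants + WT

    def test_survivor_count_near_binomial_expectation(self):
        cfg = fs.GeneratorConfig(n_strains=1000, lethality=0.423, seed=7)
        n_surv = len(fs.generate_population(cfg)) - 1
        # binomial(1000, 0.577): mean 577, sd ~15.6; allow 4 sd
        assert abs(n_surv - 577) < 4 * np.sqrt(1000 * 0.577 * 0.423)

    def test_survivorship_is_binomial_over_repetitions(self):
        """Mean survivor count over 200 seeds within 3 standard errors."""
        p = 1 - 0.423
        counts = [
            len(fs.generate_population(
                fs.GeneratorConfig(n_strains=200, lethality=0.423, seed=s)
            )) - 1
            for s in range(200)
        ]
        se = np.sqrt(200 * p * (1 - p) / 200)
        assert abs(np.mean(counts) - 200 * p) < 3 * se

    def test_carotenoids_span_configured_dose_range(self):
        lo, hi = MUTAGEN_DOSE_TABLE[("EMS", "0.1M")][1]
        cfg = fs.GeneratorConfig(n_strains=2000, seed=3)
        cars = np.array([s.true_car for s in fs.generate_population(cfg)[1:]])
        assert cars.min() >= lo and cars.max() <= hi
        # the right tail reaches near the printed dose-group maximum
        assert cars.max() > hi - 0.2
        assert cars.min() < lo + 0.2

    def test_unknown_mutagen_requires_explicit_parameters(self):
        with pytest.raises(ValueError, match="unknown mutagen"):
            fs.GeneratorConfig(mutagen="UV", dose_label="hi")
        cfg = fs.GeneratorConfig(
            mutagen="UV", dose_label="hi", lethality=0.5, car_range=(9.0, 11.0)
        )
        assert cfg.effective_lethality == 0.5

    def test_invalid_distribution_parameters_rejected(self):
        with pytest.raises(ValueError):
            fs.GeneratorConfig(car_range=(11.0, 9.0))
        with pytest.raises(ValueError):
            fs.GeneratorConfig(lethality=1.5)


class TestPlateReads:
    def test_replicate_row_count(self, population, gen_config):
        plate = fs.simulate_plate_reads(population[:20], "exponential", gen_config, 3, seed=1)
        counts = plate.groupby("strain_id").size()
        assert (counts == 3).all()
        assert set(plate.columns) == {
            "strain_id", "well", "replicate", "phase", "od625", "rfu_chla", "rfu_nilered"
        }

    def test_deterministic_given_seed(self, population, gen_config):
        a = fs.simulate_plate_reads(population, "exponential", gen_config, 3, seed=5)
        b = fs.simulate_plate_reads(population, "exponential", gen_config, 3, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_phase_rejected(self, population, gen_config):
        with pytest.raises(ValueError, match="phase"):
            fs.simulate_plate_reads(population, "lag", gen_config)

    def test_noiseless_refit_is_perfect(self, population):
        cfg = dataclasses.replace(
            fs.GeneratorConfig(), chl_noise_sd=0.0, nr_noise_sd=0.0, od_noise_sd=0.0
        )
        plate = fs.simulate_plate_reads(population[:30], "exponential", cfg, 3, seed=2)
        _, _, r2 = fs.refit_calibration(plate, population[:30], "chla")
        assert r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("channel, target_attr, n_mutants", [
        ("chla", "chl_r2_exponential", 100),
        # the Nile-red channel is configured much noisier (R^2 0.6356), so
        # the same tolerances need more strains to be statistically fair
        ("nilered", "nr_r2_exponential", 400),
    ])
    def test_calibration_recovery_exponential_phase(self, channel, target_attr, n_mutants):
        """OLS refit on exponential-phase output recovers the configured
        R^2 within +/-0.05 and the configured slope within 5%."""
        cfg = fs.GeneratorConfig(n_strains=int(n_mutants * 2.5), seed=11)
        pop = fs.generate_population(cfg)[: n_mutants + 1]  # WT + mutants
        assert len(pop) == n_mutants + 1
        plate = fs.simulate_plate_reads(pop, "exponential", cfg, 3, seed=12)
        slope, _, r2 = fs.refit_calibration(plate, pop, channel)
        assert r2 == pytest.approx(getattr(cfg, target_attr), abs=0.05)
        expected = cfg.expected_rfu_slope(channel, "exponential")
        assert slope == pytest.approx(expected, rel=0.05)

    def test_stationary_phase_correlation_is_weaker(self):
        cfg = fs.GeneratorConfig(n_strains=150, seed=21)
        pop = fs.generate_population(cfg)[:101]
        exp = fs.simulate_plate_reads(pop, "exponential", cfg, 3, seed=22)
        sta = fs.simulate_plate_reads(pop, "stationary", cfg, 3, seed=23)
        _, _, r2_exp = fs.refit_calibration(exp, pop, "chla")
        _, _, r2_sta = fs.refit_calibration(sta, pop, "chla")
        assert r2_sta < r2_exp


class TestExtractAbsorbances:
    def test_pure_chlorophyll_inversion(self):
        ext = fs.simulate_extract_absorbances(fs.PigmentProfile(ca=15.65, xcar=0.0))
        assert ext.a665 == pytest.approx(1.0)
        assert ext.a652 == pytest.approx(0.0)
        assert ext.a470 == pytest.approx(2.86 * 15.65 / 1000.0)

    def test_zero_profile_gives_zero_absorbances(self):
        ext = fs.simulate_extract_absorbances(fs.PigmentProfile(ca=0.0, xcar=0.0))
        assert (ext.a665, ext.a652, ext.a470) == (0.0, 0.0, 0.0)

    def test_negative_contents_rejected(self):
        with pytest.raises(ValueError):
            fs.simulate_extract_absorbances(fs.PigmentProfile(ca=-1.0, xcar=0.0))

    def test_roundtrip_with_nonzero_red_ratio(self):
        prof = fs.PigmentProfile(ca=12.0, xcar=5.0)
        ext = fs.simulate_extract_absorbances(prof, a652_over_a665=0.3)
        back = fs.quantify_extract(ext)
        assert back.ca == pytest.approx(12.0, rel=1e-9)
        assert back.xcar == pytest.approx(5.0, rel=1e-9)

    def test_noise_is_seeded(self):
        prof = fs.PigmentProfile(ca=10.0, xcar=4.0)
        a = fs.simulate_extract_absorbances(prof, noise_sd=0.01, seed=9)
        b = fs.simulate_extract_absorbances(prof, noise_sd=0.01, seed=9)
        assert a == b


class TestGrowthCurveGenerator:
    def test_untreated_noiseless_log_linear(self):
        curve = fs.simulate_growth_curve(0.645, 0.0, np.linspace(0, 4, 9))
        slopes = np.diff(np.log(curve.od625)) / np.diff(curve.t)
        assert np.allclose(slopes, 0.645, atol=1e-12)

    def test_dose_anchors(self):
        assert fs.dpa_growth_rate(0.645, 0.0) == pytest.approx(0.645)
        assert fs.dpa_growth_rate(0.645, 10.0) == pytest.approx(0.431)
        assert fs.dpa_growth_rate(0.645, 40.0) == pytest.approx(0.0, abs=1e-12)

    def test_dose_response_monotone_non_increasing(self):
        doses = np.linspace(0, 60, 25)
        mus = [fs.dpa_growth_rate(0.645, d) for d in doses]
        assert all(a >= b for a, b in zip(mus, mus[1:]))

    def test_above_40uM_declines(self):
        curve = fs.simulate_growth_curve(0.645, 50.0, np.linspace(0, 4, 9))
        assert np.all(np.diff(curve.od625) < 0)

    def test_seeded_noise_reproducible(self):
        t = np.linspace(0, 4, 9)
        a = fs.simulate_growth_curve(0.645, 0.0, t, noise_sd=0.05, seed=4)
        b = fs.simulate_growth_curve(0.645, 0.0, t, noise_sd=0.05, seed=4)
        assert np.array_equal(a.od625, b.od625)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fs.simulate_growth_curve(0.645, 0.0, [])


class TestStabilitySeries:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_stable_strains_change_less_than_10pct(self, population, seed):
        series = fs.simulate_stability_series(population, seed=seed)
        stable = series[series["stable"]]
        change = (stable["final_car"] - stable["initial_car"]).abs() / stable["initial_car"]
        assert (change < 0.10).all()

    def test_unstable_strain_reverts_toward_wt(self):
        strain = fs.StrainRecord("M1", "EMS", "0.1M", 13.3, 24.3, 1.3, 0.6, stable=False)
        series = fs.simulate_stability_series([strain], n_batches=8, seed=0, wt_car=10.3)
        final = series["final_car"].iloc[0]
        assert abs(final - 10.3) / 10.3 < 0.10  # reversion band
        assert abs(final - 13.3) / 13.3 > 0.10  # clearly unstable

    def test_zero_batches_rejected(self, population):
        with pytest.raises(ValueError):
            fs.simulate_stability_series(population, n_batches=0)

    def test_zero_decay_single_batch_identity(self):
        strain = fs.StrainRecord("M1", "EMS", "0.1M", 13.3, 24.3, 1.3, 0.6, stable=False)
        series = fs.simulate_stability_series(
            [strain], n_batches=1, seed=0, decay_rate=0.0
        )
        assert series["final_car"].iloc[0] == pytest.approx(13.3)


class TestColonies:
    def test_shape_and_determinism(self, population):
        a = fs.simulate_colonies(population, seed=6)
        b = fs.simulate_colonies(population, seed=6)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.columns) == ["strain_id", "size", "color_intensity"]
        assert (a["size"] > 0).all() and (a["color_intensity"] > 0).all()
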