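"""Synthetic-data generator: invariants, calibration, and known limits."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nitroclim.synth import (
    GeneratorConfig,
    generate_catchments,
    generate_daily_climate,
    generate_ensemble,
    generate_loading,
    generate_surplus,
    make_training_table,
    resolve_amplitude,
    surplus_from_components,
    true_log_response,
    true_relative_sensitivities,
    SURPLUS_FLOOR,
    _ar1,
)


class TestCatchments:
    def test_population_invariants(self):
        specs = generate_catchments(258, seed=7)
        assert len(specs) == 258
        for s in specs:
            fracs = [s.lu_developed, s.lu_cultivated, s.lu_forest_shrub, s.lu_wetland]
            assert all(0 <= f <= 100 for f in fracs)
            assert sum(fracs) <= 100 + 1e-9
            assert 0 <= s.tile_drainage <= 100
            assert s.area_km2 > 0

    def test_single_catchment(self):
        (s,) = generate_catchments(1, seed=0)
        assert s.lu_developed + s.lu_cultivated + s.lu_forest_shrub + s.lu_wetland <= 100

    def test_determinism(self):
        assert generate_catchments(50, seed=3) == generate_catchments(50, seed=3)

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            generate_catchments(0, seed=1)

    def test_tile_drainage_tracks_cultivation(self):
        specs = generate_catchments(300, seed=9)
        cult = np.array([s.lu_cultivated for s in specs])
        tile = np.array([s.tile_drainage for s in specs])
        assert np.corrcoef(cult, tile)[0, 1] > 0.5


class TestDailyClimate:
    def test_calendar_complete(self):
        spec = generate_catchments(1, 2)[0]
        s = generate_daily_climate(spec, (2000, 2000), seed=1)
        assert len(s.precip) == 366  # leap year
        assert len(s.temp) == 12
        s2 = generate_daily_climate(spec, (2001, 2001), seed=1)
        assert len(s2.precip) == 365

    def test_zero_wet_probability_gives_dry_series(self):
        spec = replace(generate_catchments(1, 2)[0], wet_prob=0.0)
        s = generate_daily_climate(spec, (2000, 2001), seed=1)
        assert (s.precip.to_numpy() == 0).all()

    def test_empty_year_range_rejected(self):
        spec = generate_catchments(1, 2)[0]
        with pytest.raises(ValueError):
            generate_daily_climate(spec, (2001, 2000), seed=1)

    def test_mean_annual_precip_matches_target(self):
        """100 simulated years hit the configured annual total within 3 SE."""
        spec = generate_catchments(1, 4)[0]
        s = generate_daily_climate(spec, (1950, 2049), seed=8)
        annual = s.precip.groupby(s.precip.index.year).sum()
        se = annual.std() / np.sqrt(len(annual))
        assert abs(annual.mean() - spec.precip_mean_mm) < 3 * se

    def test_temperature_annual_mean_matches_spec(self):
        spec = generate_catchments(1, 4)[0]
        s = generate_daily_climate(spec, (1950, 2049), seed=8)
        assert s.temp.mean() == pytest.approx(spec.temp_mean, abs=0.5)

    def test_determinism(self):
        spec = generate_catchments(1, 2)[0]
        a = generate_daily_climate(spec, (2000, 2005), seed=5)
        b = generate_daily_climate(spec, (2000, 2005), seed=5)
        pd.testing.assert_series_equal(a.precip, b.precip)
        pd.testing.assert_series_equal(a.temp, b.temp)


class TestSurplus:
    def test_budget_arithmetic(self):
        comp = pd.DataFrame(
            {"dep": [10.0], "fert": [50.0], "fix": [10.0], "man": [20.0],
             "hum": [5.0], "crop": [60.0]}
        )
        assert surplus_from_components(comp)[0] == pytest.approx(35.0)

    def test_component_closure_before_floor(self):
        spec = generate_catchments(1, 6)[0]
        sur = generate_surplus(spec, (1980, 2017), seed=3)
        raw = surplus_from_components(sur.components)
        floored = np.maximum(raw, SURPLUS_FLOOR)
        np.testing.assert_allclose(sur.n_surplus, floored, rtol=1e-12)
        assert (sur.n_surplus >= SURPLUS_FLOOR).all()

    def test_all_zero_components_floored(self):
        comp = pd.DataFrame({k: [0.0] for k in ("dep", "fert", "fix", "man", "hum", "crop")})
        assert max(surplus_from_components(comp)[0], SURPLUS_FLOOR) == SURPLUS_FLOOR

    def test_ar1_autocorrelation(self):
        """rho = 0.9 over 1,000 years: sample lag-1 autocorrelation ~ 0.9."""
        rng = np.random.default_rng(12)
        x = _ar1(rng, 1000, mean=10.0, rho=0.9, innov_sd=1.0)
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        # SE of lag-1 autocorr at rho=.9, n=1000 is about 0.014
        assert r == pytest.approx(0.9, abs=0.05)


class TestLoading:
    def _records(self, n=6):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "P_annual": rng.uniform(500, 1500, n),
                "P_MAM_p95": rng.uniform(0, 200, n),
                "T_annual": rng.uniform(0, 20, n),
                "ln_Nsurplus": np.log(rng.uniform(10, 60, n)),
                "ln_Nsurplus_lag12": np.log(rng.uniform(10, 60, n)),
                "LU_D": rng.uniform(0, 30, n),
                "LU_C": rng.uniform(0, 60, n),
                "LU_FSH": rng.uniform(0, 60, n),
                "L_TD": rng.uniform(0, 20, n),
            }
        )

    def test_noise_free_loads_equal_response(self):
        cfg = GeneratorConfig(residual_sd=0.0, precip_amplitude=4.0)
        rec = self._records()
        out = generate_loading(rec, seed=1, config=cfg)
        np.testing.assert_allclose(
            out["Q_TN"].to_numpy(), np.exp(true_log_response(rec, cfg)), rtol=1e-12
        )

    def test_reference_covariates_give_reference_load(self):
        cfg = GeneratorConfig(residual_sd=0.0, precip_amplitude=4.0)
        rec = pd.DataFrame(
            {
                "P_annual": [cfg.p_ref],
                "P_MAM_p95": [cfg.pmam_ref],
                "T_annual": [cfg.t_ref],
                "ln_Nsurplus": [np.log(cfg.surplus_ref)],
                "ln_Nsurplus_lag12": [np.log(cfg.surplus_ref)],
                "LU_D": [0.0], "LU_C": [0.0], "LU_FSH": [0.0], "L_TD": [0.0],
            }
        )
        out = generate_loading(rec, seed=1, config=cfg)
        assert out["Q_TN"][0] == pytest.approx(np.exp(cfg.ln_q_ref), rel=1e-12)

    def test_unit_surplus_elasticity_doubles_load(self):
        cfg = GeneratorConfig(
            residual_sd=0.0, precip_amplitude=4.0,
            elast_surplus=1.0, elast_surplus_lag=0.0,
        )
        rec = self._records(4)
        doubled = rec.copy()
        doubled["ln_Nsurplus"] = rec["ln_Nsurplus"] + np.log(2.0)
        q1 = generate_loading(rec, 1, cfg)["Q_TN"].to_numpy()
        q2 = generate_loading(doubled, 1, cfg)["Q_TN"].to_numpy()
        np.testing.assert_allclose(q2 / q1, 2.0, rtol=1e-12)

    def test_residual_moments(self):
        """10,000 records at sigma = 0.5: var(ln Q - generative mean) ~ 0.25."""
        cfg = GeneratorConfig(residual_sd=0.5, precip_amplitude=4.0)
        rec = self._records(10_000)
        out = generate_loading(rec, seed=9, config=cfg)
        resid = np.log(out["Q_TN"]) - out["ln_Q_true"]
        assert resid.var() == pytest.approx(0.25, rel=0.05)

    def test_missing_covariate_rejected(self):
        with pytest.raises(KeyError, match="missing covariates"):
            generate_loading(self._records().drop(columns=["T_annual"]), 1)


class TestCalibration:
    def test_noise_free_sensitivities_match_targets(self, small_config):
        """Finite-difference average sensitivities of the true response equal
        the configured targets (0.17 %/mm, 0.12 %/mm, -6.4 %/degC) within 2%."""
        table, _ = make_training_table(small_config, seed=21)
        cfg = table.attrs["generator_config"]
        targets = {
            "P_annual": cfg.target_sens_precip,
            "P_MAM_p95": cfg.target_sens_extreme,
            "T_annual": cfg.target_sens_temp,
        }
        for cov, target in targets.items():
            hi = table.copy()
            lo = table.copy()
            hi[cov] += 1.0
            lo[cov] -= 1.0
            slope = 100.0 * np.mean(
                (true_log_response(hi, cfg) - true_log_response(lo, cfg)) / 2.0
            )
            assert slope == pytest.approx(target, rel=0.02)

    def test_true_sensitivities_report_targets(self, training_table):
        table, _ = training_table
        cfg = table.attrs["generator_config"]
        sens = true_relative_sensitivities(table, cfg)
        assert sens["P_annual"] == pytest.approx(cfg.target_sens_precip, rel=1e-9)
        assert sens["T_annual"] == cfg.target_sens_temp

    def test_saturation_above_1500mm(self, training_table):
        """Marginal precip response above 1,500 mm is a small fraction of the
        response in the near-linear range below 1,200 mm."""
        table, _ = training_table
        cfg = table.attrs["generator_config"]
        amp = resolve_amplitude(table, cfg)
        s = cfg.precip_sat_scale
        slope = lambda p: amp / s * np.exp(-p / s)
        assert slope(1500.0) < 0.5 * slope(500.0)
        assert slope(2000.0) < slope(1500.0) < slope(1000.0)

    def test_conditional_lognormality(self, training_table):
        """ln(Q / generative median) passes a normality check at alpha=0.01."""
        table, _ = training_table
        resid = np.log(table["Q_TN"].to_numpy()) - table["ln_Q_true"].to_numpy()
        assert stats.normaltest(resid).pvalue > 0.01

    def test_table_determinism(self, small_config):
        a, _ = make_training_table(small_config, seed=13)
        b, _ = make_training_table(small_config, seed=13)
        pd.testing.assert_frame_equal(a, b)


class TestEnsemble:
    def test_dimensions_and_segments(self):
        cfg = GeneratorConfig()
        spec = generate_catchments(1, 5)[0]
        ens = generate_ensemble(
            spec, None, n_members=3, seed=1, config=cfg,
            hist_range=(1995, 2014), future_range=(2015, 2034),
        )
        assert set(ens) == {"ssp126", "ssp245", "ssp585"}
        total = sum(len(v) for v in ens.values())
        assert total == 9
        for members in ens.values():
            for m in members:
                yrs = m.series.years()
                assert yrs.min() == 1995 and yrs.max() == 2034

    def test_additive_temp_bias_shifts_reference_mean(self):
        spec = generate_catchments(1, 5)[0]
        ens = generate_ensemble(
            spec, None, 2, seed=3, hist_range=(1981, 2014),
            future_range=(2015, 2020), temp_biases=[2.0, 0.0],
        )["ssp126"]
        biased, neutral = ens
        ref = slice(None)
        delta = biased.series.temp.mean() - biased.truth.temp.mean()
        assert delta == pytest.approx(2.0, abs=1e-12)

    def test_neutral_bias_member_matches_truth(self):
        spec = generate_catchments(1, 5)[0]
        ens = generate_ensemble(
            spec, None, 2, seed=3, hist_range=(1981, 2014),
            future_range=(2015, 2020), temp_biases=[0.0, 0.0],
            precip_biases=[1.0, 1.0],
        )["ssp126"]
        m = ens[0]
        pd.testing.assert_series_equal(m.series.precip, m.truth.precip)
        pd.testing.assert_series_equal(m.series.temp, m.truth.temp)

    def test_rejects_single_member(self):
        spec = generate_catchments(1, 5)[0]
        with pytest.raises(ValueError, match="at least 2"):
            generate_ensemble(spec, None, n_members=1, seed=1)
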