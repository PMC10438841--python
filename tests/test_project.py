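"""Covariate derivation, effect decomposition, ensemble logic, aggregation."""

import numpy as np
import pandas as pd
import pytest

from nitroclim.climate import ClimateSeries, PeriodDefinition
from nitroclim.gam import TermSpec, fit_loading_model
from nitroclim.project import (
    aggregate_region,
    classify_tradeoff,
    decompose_effects,
    derive_covariates,
    ensemble_stats,
    project_member,
)
from nitroclim.synth import generate_catchments, generate_daily_climate


def _toy_series(mam_values=(10.0, 96.0, 100.0), temp_c=10.0, year=2000):
    """One complete year: all days dry except three April days."""
    idx = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    p = pd.Series(0.0, index=idx)
    for day, v in zip(("04-10", "04-15", "04-20"), mam_values):
        p.loc[f"{year}-{day}"] = v
    t = pd.Series(
        temp_c, index=pd.period_range(f"{year}-01", f"{year}-12", freq="M")
    )
    return ClimateSeries("W1", p, t)


class TestDeriveCovariates:
    def test_extreme_metric_sums_full_exceeding_amounts(self):
        """Days {10, 96, 100} against threshold 95: metric = 96+100 = 196."""
        s = _toy_series()
        cov = derive_covariates(s, (2000, 2000), threshold=95.0)
        assert cov.loc[2000, "P_MAM_p95"] == pytest.approx(196.0)
        assert cov.loc[2000, "P_annual"] == pytest.approx(206.0)

    def test_no_exceedance_gives_zero(self):
        s = _toy_series(mam_values=(10.0, 20.0, 30.0))
        cov = derive_covariates(s, (2000, 2000), threshold=95.0)
        assert cov.loc[2000, "P_MAM_p95"] == 0.0

    def test_constant_monthly_temperature(self):
        cov = derive_covariates(_toy_series(temp_c=10.0), (2000, 2000), threshold=95.0)
        assert cov.loc[2000, "T_annual"] == pytest.approx(10.0)

    def test_threshold_from_reference_wet_days(self):
        spec = generate_catchments(1, 3)[0]
        s = generate_daily_climate(spec, (1981, 2012), seed=2)
        cov = derive_covariates(s, (1981, 2010))
        wet = s.subset((1981, 2010)).precip
        wet = wet[wet > 0.1]
        thr = np.percentile(wet, 95)
        mam = s.precip[(s.precip.index.month >= 3) & (s.precip.index.month <= 5)]
        year = 2011
        expected = mam[(mam.index.year == year) & (mam > thr)].sum()
        assert cov.loc[year, "P_MAM_p95"] == pytest.approx(expected)

    def test_incomplete_year_omitted(self):
        s = _toy_series()
        trimmed = ClimateSeries("W1", s.precip.iloc[:300], s.temp)
        cov = derive_covariates(trimmed, (2000, 2000), threshold=95.0)
        assert len(cov) == 0


def _two_cov_model():
    rng = np.random.default_rng(2)
    n = 500
    df = pd.DataFrame(
        {
            "P_annual": rng.uniform(400, 1600, n),
            "P_MAM_p95": rng.uniform(0, 200, n),
            "T_annual": rng.uniform(0, 20, n),
            "S": rng.uniform(1, 3, n),
        }
    )
    df["Q_TN"] = np.exp(
        8.0 + 0.0008 * df["P_annual"] + 0.001 * df["P_MAM_p95"]
        - 0.06 * df["T_annual"] + 0.5 * df["S"]
    )
    terms = [TermSpec(c, "linear") for c in ("P_annual", "P_MAM_p95", "T_annual", "S")]
    return fit_loading_model(df, terms), df


class TestProjection:
    def test_identical_climate_gives_zero_change(self):
        model, df = _two_cov_model()
        clim = df.iloc[:30][["P_annual", "P_MAM_p95", "T_annual"]]
        fixed = {"S": 2.0}
        assert project_member(model, clim, clim, fixed) == pytest.approx(0.0, abs=1e-10)

    def test_decomposition_identity_single_year(self):
        """(1 + dQc/100) = (1 + dQp/100)(1 + dQt/100) exactly for 1-y windows."""
        model, df = _two_cov_model()
        base = df.iloc[[0]][["P_annual", "P_MAM_p95", "T_annual"]]
        fut = df.iloc[[1]][["P_annual", "P_MAM_p95", "T_annual"]]
        fixed = {"S": 2.0}
        dc = project_member(model, base, fut, fixed)
        dp, dt = decompose_effects(model, base, fut, fixed)
        assert (1 + dc / 100) == pytest.approx((1 + dp / 100) * (1 + dt / 100), rel=1e-10)

    def test_decomposition_identity_thirty_year_windows(self):
        """Period averaging breaks exact multiplicativity by < 1% absolute."""
        model, df = _two_cov_model()
        rng = np.random.default_rng(7)

        def window(p_mean, t_mean):
            return pd.DataFrame(
                {
                    "P_annual": rng.normal(p_mean, 90.0, 30),
                    "P_MAM_p95": rng.normal(60.0, 20.0, 30).clip(0),
                    "T_annual": rng.normal(t_mean, 0.8, 30),
                }
            )

        base = window(1000.0, 11.0)
        fut = window(1060.0, 13.0)
        fixed = {"S": 2.0}
        dc = project_member(model, base, fut, fixed)
        dp, dt = decompose_effects(model, base, fut, fixed)
        composed = 100 * ((1 + dp / 100) * (1 + dt / 100) - 1)
        assert abs(dc - composed) < 1.0

    def test_multiplicative_composition_example(self):
        """+10% P-effect and -10% T-effect compose to about -1%."""
        assert 100 * (1.10 * 0.90 - 1) == pytest.approx(-1.0)

    def test_warming_change_consistent_with_sensitivity(self):
        """Uniform +1 degC: dQ matches the model's relative T sensitivity."""
        model, df = _two_cov_model()
        cols = ["P_annual", "P_MAM_p95", "T_annual"]
        base = df.iloc[:30][cols]
        fut = base.assign(T_annual=base["T_annual"] + 1.0)
        dq = project_member(model, base, fut, {"S": 2.0})
        assert dq == pytest.approx(100 * (np.exp(-0.06) - 1), rel=1e-4)

    def test_change_invariant_to_load_units(self):
        model, df = _two_cov_model()
        cols = ["P_annual", "P_MAM_p95", "T_annual"]
        base, fut = df.iloc[:10][cols], df.iloc[10:20][cols]
        scaled = df.copy()
        scaled["Q_TN"] /= 1000.0
        m2 = fit_loading_model(
            scaled,
            [TermSpec(c, "linear") for c in ("P_annual", "P_MAM_p95", "T_annual", "S")],
        )
        d1 = project_member(model, base, fut, {"S": 2.0})
        d2 = project_member(m2, base, fut, {"S": 2.0})
        assert d1 == pytest.approx(d2, rel=1e-8)


def _member_frame(values, p_only=None, t_only=None):
    n = len(values)
    return pd.DataFrame(
        {
            "watershed_id": "W1",
            "scenario": "ssp245",
            "member": [f"m{i}" for i in range(n)],
            "dQ_combined": values,
            "dQ_P_only": p_only if p_only is not None else values,
            "dQ_T_only": t_only if t_only is not None else values,
        }
    )


class TestEnsembleStats:
    def test_thirteen_of_sixteen_is_robust(self):
        vals = [-5.0] * 13 + [1.0, 2.0, 3.0]
        out = ensemble_stats(_member_frame(vals))
        assert out.loc[0, "agreement"] == pytest.approx(13 / 16)
        assert bool(out.loc[0, "robust"]) is True

    def test_twelve_of_sixteen_is_stippled(self):
        vals = [-5.0] * 12 + [1.0, 2.0, 3.0, 4.0]
        out = ensemble_stats(_member_frame(vals))
        assert out.loc[0, "agreement"] == pytest.approx(0.75)
        assert bool(out.loc[0, "robust"]) is False

    def test_identical_members(self):
        out = ensemble_stats(_member_frame([-2.0] * 16))
        assert out.loc[0, "agreement"] == 1.0
        assert out.loc[0, "median_combined"] == -2.0

    def test_member_order_invariance(self):
        vals = [-5.0] * 13 + [1.0, 2.0, 3.0]
        a = ensemble_stats(_member_frame(vals))
        rng = np.random.default_rng(0)
        b = ensemble_stats(
            _member_frame(list(rng.permutation(vals)))
        )
        pd.testing.assert_frame_equal(a, b)

    def test_tradeoff_classes_partition(self):
        cases = [(-3.0, -1.0), (2.0, -1.0), (2.0, 3.0), (-1.0, 0.5), (0.0, 0.0)]
        for p, c in cases:
            cls = classify_tradeoff(p, c)
            assert cls in ("offset", "compound-decrease", "net-increase")
        assert classify_tradeoff(2.0, -1.0) == "offset"
        assert classify_tradeoff(-3.0, -1.0) == "compound-decrease"
        assert classify_tradeoff(2.0, 3.0) == "net-increase"


class TestAggregateRegion:
    def test_weighted_two_watershed_example(self):
        """Baseline loads 90 and 10 with -10% and +10%: regional -8%."""
        base = pd.DataFrame({"m0": [90.0, 10.0]}, index=["a", "b"])
        fut = pd.DataFrame({"m0": [81.0, 11.0]}, index=["a", "b"])
        out = aggregate_region(base, fut)
        assert out["dQ_region"].iloc[0] == pytest.approx(-8.0)

    def test_single_watershed_equals_own_change(self):
        base = pd.DataFrame({"m0": [50.0]}, index=["a"])
        fut = pd.DataFrame({"m0": [55.0]}, index=["a"])
        assert aggregate_region(base, fut)["dQ_region"].iloc[0] == pytest.approx(10.0)

    def test_median_matches_brute_force(self):
        rng = np.random.default_rng(4)
        base = pd.DataFrame(
            rng.uniform(10, 100, (20, 16)),
            index=[f"w{i}" for i in range(20)],
            columns=[f"m{j}" for j in range(16)],
        )
        fut = base * rng.uniform(0.8, 1.2, (20, 16))
        out = aggregate_region(base, fut)
        brute = [
            100 * (fut[c].sum() - base[c].sum()) / base[c].sum() for c in base.columns
        ]
        assert out.attrs["median"] == pytest.approx(np.median(brute))
        np.testing.assert_allclose(out["dQ_region"].to_numpy(), brute)
        # regional change bracketed by watershed-level extremes per member
        per_ws = 100 * (fut - base) / base
        for c in base.columns:
            assert per_ws[c].min() - 1e-9 <= out.loc[c, "dQ_region"] <= per_ws[c].max() + 1e-9

    def test_empty_region_rejected(self):
        empty = pd.DataFrame()
        with pytest.raises(ValueError, match="empty"):
            aggregate_region(empty, empty)
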