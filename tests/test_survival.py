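"""Median dichotomization, dataset assembly and the Breslow Cox fitter."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from immunotopo import (SimParams, build_survival_dataset, cox_fit,
                        dichotomize_at_median, generate_cohort)


class TestDichotomize:
    def test_even_split(self):
        out = dichotomize_at_median(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert out.tolist() == ["low", "low", "high", "high"]

    def test_median_ties_go_low(self):
        out = dichotomize_at_median(pd.Series([0.0, 0.0, 0.0, 5.0]))
        assert out.tolist() == ["low", "low", "low", "high"]

    def test_distinct_values_split_in_halves(self):
        rng = np.random.default_rng(0)
        v = pd.Series(rng.permutation(np.arange(173, dtype=float)))
        out = dichotomize_at_median(v)
        assert (out == "high").sum() in (86, 87)

    def test_missing_propagates(self):
        out = dichotomize_at_median(pd.Series([1.0, np.nan, 3.0]))
        assert out.isna().tolist() == [False, True, False]

    def test_all_missing_error(self):
        with pytest.raises(ValueError):
            dichotomize_at_median(pd.Series([np.nan, np.nan]))


def _clinical(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "case_id": [f"c{i}" for i in range(n)],
        "morphology": rng.choice(["I-type", "PB-type"], n),
        "age": rng.normal(70, 5, n).round(1),
        "t_stage": rng.choice(["T1_T2", "T3_T4"], n),
        "n_stage": rng.choice(["negative", "positive"], n),
        "grade": rng.choice(["well_moderate", "poor"], n),
        "adjuvant": rng.random(n) < 0.5,
        "vascular_invasion": rng.random(n) < 0.5,
        "lymphatic_invasion": rng.random(n) < 0.5,
        "perineural_growth": rng.random(n) < 0.5,
        "neoadjuvant": [i == 0 for i in range(n)],
        "lost_to_followup": False,
        "early_postop_death": False,
        "os_months": rng.uniform(1, 100, n).round(2),
        "event": rng.random(n) < 0.7,
    })


class TestBuildSurvivalDataset:
    def _exposure(self, clin):
        return pd.Series("high", index=clin["case_id"]).where(
            np.arange(len(clin)) % 2 == 0, "low")

    def test_cap_recodes_late_deaths_as_censored(self):
        clin = _clinical()
        clin.loc[2, ["os_months", "event"]] = [72.0, True]
        clin.loc[3, ["os_months", "event"]] = [59.0, True]
        ds = build_survival_dataset(clin, self._exposure(clin), cap=60.0)
        ds = ds.set_index("case_id")
        assert ds.loc["c2", "time"] == 60.0 and not ds.loc["c2", "event"]
        assert ds.loc["c3", "time"] == 59.0 and ds.loc["c3", "event"]

    def test_neoadjuvant_case_absent(self):
        clin = _clinical()
        ds = build_survival_dataset(clin, self._exposure(clin))
        assert "c0" not in set(ds["case_id"])

    def test_morphology_covariate_only_in_entire_cohort(self):
        clin = _clinical(40)
        exp = self._exposure(clin)
        ds_all = build_survival_dataset(clin, exp, stratum="all")
        ds_pb = build_survival_dataset(clin, exp, stratum="PB-type")
        assert "morphology" in ds_all.columns
        assert "morphology" not in ds_pb.columns
        assert set(ds_pb["case_id"]) <= set(
            clin.loc[clin["morphology"] == "PB-type", "case_id"])


def breslow_loglik_oracle(beta, time, event, x):
    """Direct O(n²) Breslow partial log-likelihood (univariable)."""
    ll = 0.0
    for t in np.unique(time[event]):
        dead = event & (time == t)
        risk = time >= t
        ll += beta * x[dead].sum() - dead.sum() * math.log(
            np.exp(beta * x[risk]).sum())
    return ll


def _two_group_exponential(seed=0, n=120):
    rng = np.random.default_rng(seed)
    x = (np.arange(n) % 2).astype(float)
    t = rng.exponential(1.0 / np.exp(0.8 * x))
    event = np.ones(n, dtype=bool)
    return pd.DataFrame({"time": t, "event": event, "exposure": x})


class TestCoxFit:
    def test_matches_grid_search_oracle_on_tie_free_data(self):
        """Univariable β̂ equals the 1-D maximizer of the Breslow partial
        likelihood found independently by scalar optimization."""
        data = _two_group_exponential()
        res = cox_fit(data, ["exposure"])
        assert res.converged
        t = data["time"].to_numpy()
        e = data["event"].to_numpy()
        x = data["exposure"].to_numpy()
        opt = minimize_scalar(
            lambda b: -breslow_loglik_oracle(b, t, e, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.coef["exposure"] == pytest.approx(opt.x, abs=1e-6)

    def test_null_recovery_large_sample(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0, n)
        data = pd.DataFrame({"time": t, "event": True, "exposure": x})
        res = cox_fit(data, ["exposure"])
        hr = float(np.exp(res.coef["exposure"]))
        assert 0.85 <= hr <= 1.18

    def test_reciprocal_symmetry(self):
        data = _two_group_exponential(seed=3)
        res = cox_fit(data, ["exposure"])
        flipped = data.assign(exposure=1.0 - data["exposure"])
        res2 = cox_fit(flipped, ["exposure"])
        est, est2 = (res.hazard_estimate(), res2.hazard_estimate())
        assert est2.hr == pytest.approx(1.0 / est.hr, rel=1e-6)
        assert est2.ci_low == pytest.approx(1.0 / est.ci_high, rel=1e-6)
        assert est2.ci_high == pytest.approx(1.0 / est.ci_low, rel=1e-6)

    def test_time_scale_invariance(self):
        data = _two_group_exponential(seed=4)
        res = cox_fit(data, ["exposure"])
        scaled = data.assign(time=data["time"] * 37.5)
        res2 = cox_fit(scaled, ["exposure"])
        assert res2.coef["exposure"] == pytest.approx(
            res.coef["exposure"], abs=1e-8)

    def test_separation_flagged_not_finite(self):
        # exposure perfectly orders the survival times -> monotone likelihood
        n = 30
        x = np.concatenate([np.zeros(15), np.ones(15)])
        t = np.concatenate([np.linspace(1, 2, 15), np.linspace(10, 20, 15)])
        data = pd.DataFrame({"time": t, "event": True, "exposure": x})
        res = cox_fit(data, ["exposure"])
        assert res.flag == "separation"
        est = res.hazard_estimate()
        assert np.isnan(est.hr)
        assert est.ci_high == np.inf

    def test_collinear_columns_named(self):
        data = _two_group_exponential(seed=5)
        data["dup"] = data["exposure"] * 2.0
        with pytest.raises(ValueError, match="dup|exposure"):
            cox_fit(data, ["exposure", "dup"])

    def test_matches_lifelines_with_breslow_ties(self):
        """Independent cross-check against an established fitter."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(7)
        n = 200
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = np.round(rng.exponential(1.0 / np.exp(0.5 * x1 - 0.3 * x2)), 2)
        t = np.clip(t, 0.01, None)  # rounding creates occasional ties
        c = rng.random(n) < 0.25
        data = pd.DataFrame({"time": t, "event": ~c, "x1": x1, "x2": x2})
        res = cox_fit(data, ["x1", "x2"])
        cph = CoxPHFitter()
        cph.fit(data, duration_col="time", event_col="event")
        # lifelines uses Efron tie handling; with only occasional ties the
        # Breslow and Efron estimates agree closely
        assert res.coef["x1"] == pytest.approx(
            cph.params_["x1"], abs=0.02)
        assert res.coef["x2"] == pytest.approx(
            cph.params_["x2"], abs=0.02)
        assert res.se["x1"] == pytest.approx(
            cph.standard_errors_["x1"], abs=0.02)


class TestParameterRecovery:
    def test_recovers_true_hazard_ratio(self, survival_params):
        """Generator + fitter round trip: true HR 0.6 on the latent
        high-infiltration group is recovered within [0.45, 0.80]."""
        params = SimParams(**{**survival_params, "seed": 123})
        cohort = generate_cohort(params)
        truth = cohort.case_truth.set_index("case_id")
        exposure = truth["high_infiltration"].map(
            {True: "high", False: "low"})
        ds = build_survival_dataset(cohort.clinical, exposure, cap=60.0,
                                    covariates=())
        res = cox_fit(ds, ["exposure"])
        est = res.hazard_estimate()
        assert 0.45 <= est.hr <= 0.80
        assert est.ci_low <= 0.6 <= est.ci_high

    def test_event_rate_ratio_matches_exp_beta(self):
        """With Weibull shape 1 and one binary covariate, the ratio of
        event hazards matches exp(β) within Monte-Carlo error."""
        params = SimParams(
            n_cases=4000, cores_per_case=0, benign_case_fraction=0.0,
            betas={"high_infiltration": math.log(0.5)},
            baseline_weibull_shape=1.0, baseline_weibull_scale=50.0,
            admin_censor_months=1e9, seed=77,
        )
        cohort = generate_cohort(params)
        truth = cohort.case_truth
        t = truth["uncensored_time"].to_numpy()
        high = truth["high_infiltration"].to_numpy()
        # exponential rates -> 1/mean estimates the hazard
        ratio = (1.0 / t[high].mean()) / (1.0 / t[~high].mean())
        assert ratio == pytest.approx(0.5, rel=0.08)
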