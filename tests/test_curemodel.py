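"""Mixture cure model: E-step algebra, M-step oracles, EM reductions,
post-estimation summaries, and bootstrap inference."""

import warnings

import numpy as np
import pytest
from scipy.special import expit, logit

from curemix import datagen
from curemix.curemodel import (
    CureDesign,
    bootstrap_inference,
    em_fit,
    estep_weights,
    median_uncured_time,
    mean_marginal_survival,
    mstep_incidence,
    mstep_latency,
    observed_loglik,
    predict_cure_probability,
    predict_marginal_survival,
    strata_summary,
    uncured_survival,
)
from curemix.survcore import (
    ConvergenceWarning,
    DiscreteBaseline,
    SurvivalSample,
    cox_fit,
)

from conftest import build_simple_design


def _design(times, events, z_extra=None, x=None):
    n = len(times)
    z = np.ones((n, 1)) if z_extra is None else np.column_stack(
        [np.ones(n), np.asarray(z_extra, float)])
    x_arr = np.zeros((n, 0)) if x is None else np.asarray(x, float)
    return CureDesign(z, x_arr, SurvivalSample(times, events))


class TestEstep:
    def test_events_always_weight_one(self):
        d = _design([1.0, 2.0, 3.0], [1, 1, 0])
        base = DiscreteBaseline([1.0, 2.0], [0.3, 0.5], zero_tail=True)
        w = estep_weights([0.0], [], base, d)
        assert w[0] == 1.0 and w[1] == 1.0

    def test_direct_arithmetic(self):
        # pi=0.8, Su=0.25 -> w = 0.8*0.25 / (0.2 + 0.8*0.25) = 0.5
        d = _design([1.5], [0])
        lam = -np.log(0.25)  # cumhaz such that Su(1.5) = 0.25
        base = DiscreteBaseline([1.0, 2.0], [lam, 0.1], zero_tail=True)
        w = estep_weights([float(logit(0.8))], [], base, d)
        assert w[0] == pytest.approx(0.5, abs=1e-12)

    def test_w_equals_pi_before_first_event(self):
        # censored before any event: Su=1, so w = pi
        d = _design([0.5], [0])
        base = DiscreteBaseline([1.0], [0.7], zero_tail=True)
        w = estep_weights([float(logit(0.37))], [], base, d)
        assert w[0] == pytest.approx(0.37, abs=1e-12)

    def test_zero_denominator_guarded(self):
        # pi ~ 1 and censored beyond the last event (Su = 0): contradictory
        # configuration resolved to w = 0
        d = _design([5.0], [0])
        base = DiscreteBaseline([1.0], [0.7], zero_tail=True)
        w = estep_weights([40.0], [], base, d)
        assert w[0] == 0.0

    def test_mixture_identity_of_marginal_curve(self, simple_cure_spec, quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        design = build_simple_design(cohort)
        fit = em_fit(design, tol=1e-6)
        z_new = np.array([1.0, 0.5, 1.0])
        x_new = np.array([0.5, 1.0])
        marginal = predict_marginal_survival(fit, z_new, x_new)
        su = uncured_survival(fit, x_new)
        pi = float(expit(z_new @ fit.b))
        assert np.allclose(marginal.values, (1 - pi) + pi * su.values, atol=1e-14)
        assert marginal.values.min() >= 1 - pi - 1e-12  # floor at cure prob


class TestMstepIncidence:
    def test_constant_half_weights_give_zero_logit(self):
        d = _design([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        b = mstep_incidence(d, [0.5, 0.5, 0.5, 0.5])
        assert b[0] == pytest.approx(0.0, abs=1e-8)

    def test_all_one_weights_cap_flagged(self):
        d = _design([1.0, 2.0], [1, 1])
        with pytest.warns(ConvergenceWarning):
            b = mstep_incidence(d, [1.0, 1.0])
        assert b[0] == 20.0

    def test_matches_grid_search_oracle(self):
        # intercept-only fractional responses: compare against brute-force
        # maximization of the 1-parameter likelihood on a fine grid
        rng = np.random.default_rng(6)
        w = rng.random(40)
        d = _design(np.arange(1, 41, dtype=float), np.zeros(40, dtype=int))
        b = mstep_incidence(d, w)
        grid = np.linspace(-5, 5, 200_001)
        p = expit(grid)[None, :]
        ll = (w[:, None] * np.log(p) + (1 - w[:, None]) * np.log(1 - p)).sum(0)
        assert b[0] == pytest.approx(grid[np.argmax(ll)], abs=1e-4)


class TestMstepLatency:
    def test_unit_weights_reduce_to_cox(self):
        rng = np.random.default_rng(1)
        n = 150
        x = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        e = (rng.random(n) < 0.7).astype(int)
        d = _design(t, e, x=x)
        beta, base, _ = mstep_latency(d, np.ones(n))
        ref = cox_fit(SurvivalSample(t, e), x)
        assert np.allclose(beta, ref.beta, atol=1e-10)
        assert np.allclose(base.jumps, ref.baseline_hazard.jumps, atol=1e-10)

    def test_zero_weight_censored_equals_events_only_fit(self):
        rng = np.random.default_rng(2)
        n = 120
        x = rng.normal(size=(n, 1))
        t = rng.exponential(np.exp(-0.5 * x[:, 0]))
        e = (rng.random(n) < 0.6).astype(int)
        w = np.where(e == 1, 1.0, 0.0)
        d = _design(t, e, x=x)
        beta, _, _ = mstep_latency(d, w)
        ref = cox_fit(SurvivalSample(t[e == 1], e[e == 1]), x[e == 1])
        assert np.allclose(beta, ref.beta, atol=1e-9)

    def test_zero_tail_contract(self):
        d = _design([1.0, 2.0, 5.0], [1, 1, 0], x=None)
        _, base, _ = mstep_latency(d, np.array([1.0, 1.0, 0.5]))
        assert base.surv_at(2.0) > 0.0
        assert base.surv_at(2.0000001) == 0.0


class TestObservedLoglik:
    def test_single_censored_at_origin_is_zero(self):
        d = _design([0.0], [0])
        base = DiscreteBaseline([], [], zero_tail=True)
        assert observed_loglik([0.0], [], base, d) == pytest.approx(0.0)

    def test_single_event_hand_computation(self):
        # one event at t=1, pi ~ 1: contribution log(dL) + 0 - L(1)*1 with
        # dL = L = 1 (Breslow on one subject) -> loglik = -1
        d = _design([1.0], [1])
        base = DiscreteBaseline([1.0], [1.0], zero_tail=True)
        ll = observed_loglik([40.0], [], base, d)
        assert ll == pytest.approx(-1.0, abs=1e-9)

    def test_additivity_under_duplication(self):
        t = np.array([0.7, 1.3, 2.9])
        e = np.array([1, 0, 1])
        base = DiscreteBaseline([0.7, 2.9], [0.4, 0.9], zero_tail=True)
        d1 = _design(t, e)
        d2 = _design(np.tile(t, 2), np.tile(e, 2))
        l1 = observed_loglik([0.3], [], base, d1)
        l2 = observed_loglik([0.3], [], base, d2)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)


class TestEMFit:
    def test_forced_uncured_reduces_to_cox(self, quiet_warnings):
        rng = np.random.default_rng(10)
        n = 400
        x = rng.normal(size=(n, 2))
        t = rng.exponential(np.exp(-(x @ np.array([0.6, -0.4]))))
        c = rng.uniform(0.5, 4, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        d = CureDesign(np.ones((n, 1)), x, SurvivalSample(obs, ev))
        fit = em_fit(d, pi_fixed=1.0)
        ref = cox_fit(SurvivalSample(obs, ev), x)
        assert np.allclose(fit.beta, ref.beta, atol=1e-6)

    def test_no_cure_data_estimates_tiny_cure_fraction(self, quiet_warnings):
        spec = datagen.CohortSpec(
            n=5000,
            covariates=[datagen.Continuous("x1", "normal",
                                           {"loc": 0, "scale": 1})],
            b={"intercept": 20.0},  # all uncured
            beta={"x1": 0.5},
            baseline=datagen.WeibullBaseline.from_median(1.0, 1.2),
            censor_window=(6.0, 10.0),
            seed=3,
        )
        cohort = datagen.simulate_cohort(spec)
        df = cohort.table
        d = CureDesign.build(df, [], ["x1"])
        fit = em_fit(d)
        ref = cox_fit(SurvivalSample(df.time_years.to_numpy(),
                                     df.event_metastasis.to_numpy()),
                      df[["x1"]].to_numpy())
        cure = float(np.mean(predict_cure_probability(fit)))
        assert cure < 0.02
        assert np.allclose(fit.beta, ref.beta, atol=1e-3 + 3e-2 * abs(ref.beta[0]))

    def test_loglik_trace_monotone(self, simple_cure_spec, quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        fit = em_fit(build_simple_design(cohort))
        diffs = np.diff(fit.loglik_trace)
        assert diffs.min() >= -1e-8 * (1 + np.abs(fit.loglik_trace[:-1]).max())

    def test_weak_identifiability_warns(self):
        # every censoring before the last event: plateau empty
        d = _design([1.0, 2.0, 3.0], [1, 0, 1])
        with pytest.warns(UserWarning, match="cure fraction"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                em_fit(d, max_iter=5)

    def test_zero_tail_on_fitted_baseline(self, simple_cure_spec, quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        fit = em_fit(build_simple_design(cohort))
        last_event = cohort.table.loc[
            cohort.table.event_metastasis == 1, "time_years"].max()
        assert fit.S0.at(last_event * 1.0000001) == 0.0
        assert fit.S0.at(last_event) > 0.0


class TestSummaries:
    def test_cure_probability_all_zero_coefficients(self):
        d = _design([1.0, 2.0], [1, 0])
        base = DiscreteBaseline([1.0], [0.5], zero_tail=True)
        fit = em_fit(d, max_iter=1, init=([0.0], [], base))
        fit.b = np.zeros(1)
        assert np.allclose(predict_cure_probability(fit), 0.5)

    def test_median_from_step_curve(self, simple_cure_spec, quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        fit = em_fit(build_simple_design(cohort))
        med = median_uncured_time(fit, np.zeros(2))
        su = uncured_survival(fit, np.zeros(2))
        assert su.at(med) <= 0.5
        assert su.at(med * 0.999) > 0.5

    def test_median_undefined_sentinel(self):
        d = _design([1.0, 2.0], [1, 0])
        base = DiscreteBaseline([1.0], [0.1], zero_tail=False)  # floors at 0.9
        fit = em_fit(d, max_iter=1, init=([0.0], [], base))
        fit.baseline = base
        assert np.isnan(median_uncured_time(fit))

    def test_exponential_latency_median_closed_form(self, quiet_warnings):
        # rate lambda exponential latency: median -> ln 2 / lambda
        lam_med = 1.6
        spec = datagen.CohortSpec(
            n=10_000,
            covariates=[datagen.Continuous("x1", "normal",
                                           {"loc": 0, "scale": 1})],
            b={"intercept": float(logit(0.5))},
            beta={},
            baseline=datagen.WeibullBaseline.from_median(lam_med, 1.0),
            censor_window=(6.0, 10.0),
            seed=4,
        )
        cohort = datagen.simulate_cohort(spec)
        d = CureDesign.build(cohort.table, [], [])
        fit = em_fit(d)
        med = median_uncured_time(fit)
        assert med == pytest.approx(lam_med, rel=0.05)

    def test_marginal_survival_limits(self):
        d = _design([1.0, 2.0], [1, 0])
        base = DiscreteBaseline([1.0], [0.5], zero_tail=True)
        fit = em_fit(d, max_iter=1, init=([0.0], [], base))
        fit.b = np.array([-40.0])  # pi ~ 0
        flat = predict_marginal_survival(fit, [1.0], [])
        assert np.allclose(flat.values, 1.0, atol=1e-12)
        fit.b = np.array([40.0])  # pi ~ 1
        su = uncured_survival(fit)
        curve = predict_marginal_survival(fit, [1.0], [])
        assert np.allclose(curve.values, su.values, atol=1e-12)

    def test_ensemble_mean_curve_averages_individuals(self, simple_cure_spec,
                                                      quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        design = build_simple_design(cohort)
        fit = em_fit(design)
        mean_curve = mean_marginal_survival(fit)
        # recompute by brute-force averaging of per-subject curves
        t_probe = np.median(design.sample.times)
        per = [
            predict_marginal_survival(fit, design.z[i], design.x[i]).at(t_probe)
            for i in range(0, design.n, 97)
        ]
        full = [
            predict_marginal_survival(fit, design.z[i], design.x[i]).at(t_probe)
            for i in range(design.n)
        ]
        assert mean_curve.at(t_probe) == pytest.approx(np.mean(full), abs=1e-10)
        assert len(per) > 3  # sanity on the subsample loop


class TestBootstrap:
    def test_reproducible_for_fixed_seed(self, quiet_warnings):
        cohort = datagen.simulate_cohort(
            datagen.CohortSpec(
                n=250,
                covariates=[datagen.Continuous("x1", "normal",
                                               {"loc": 0, "scale": 1})],
                b={"intercept": -1.0, "x1": 0.5},
                beta={"x1": 0.5},
                baseline=datagen.WeibullBaseline.from_median(1.6, 1.2),
                censor_window=(1.0, 8.5),
                seed=5,
            ))
        d = CureDesign.build(cohort.table, ["x1"], ["x1"])
        i1 = bootstrap_inference(d, B=50, seed=123)
        i2 = bootstrap_inference(d, B=50, seed=123)
        assert np.array_equal(i1.b_reps, i2.b_reps)
        assert np.array_equal(i1.beta_reps, i2.beta_reps)

    def test_identical_rows_give_zero_se(self, quiet_warnings):
        # bootstrap of a two-point degenerate cohort: replicate fits are
        # identical whenever both rows are drawn, giving SD ~ 0
        n = 60
        t = np.tile([1.0, 5.0], n // 2)
        e = np.tile([1, 0], n // 2)
        d = _design(t, e)
        inf = bootstrap_inference(d, B=50, seed=1,
                                  em_kwargs={"max_iter": 50})
        assert np.all(inf.b_se < 0.3)  # tight around the common value

    def test_strata_summary_whole_cohort_equals_global(self, simple_cure_spec,
                                                       quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        design = build_simple_design(cohort)
        fit = em_fit(design)
        summ = strata_summary(fit, {"all": np.ones(design.n, dtype=bool)})
        row = summ.table.iloc[0]
        assert row["cure_pct"] == pytest.approx(
            100 * np.mean(predict_cure_probability(fit)))
        assert row["n"] == design.n

    def test_strata_ordering_matches_generating_signs(self, quiet_warnings):
        # positive incidence coefficient on arm=b -> arm b less often cured
        spec = datagen.CohortSpec(
            n=5000,
            covariates=[datagen.Categorical("arm", ["a", "b"], [0.5, 0.5])],
            b={"intercept": -1.2, "arm=b": 0.8},
            beta={},
            baseline=datagen.WeibullBaseline.from_median(1.6, 1.2),
            censor_window=(1.0, 8.5),
            seed=6,
        )
        cohort = datagen.simulate_cohort(spec)
        df = cohort.table.copy()
        df["arm_b"] = (df["arm"] == "b").astype(float)
        design = CureDesign.build(df, ["arm_b"], [])
        fit = em_fit(design)
        masks = {"arm_a": (df["arm_b"] == 0).to_numpy(),
                 "arm_b": (df["arm_b"] == 1).to_numpy()}
        summ = strata_summary(fit, masks).table.set_index("stratum")
        assert summ.loc["arm_a", "cure_pct"] > summ.loc["arm_b", "cure_pct"]

    def test_empty_stratum_reported_without_estimates(self, simple_cure_spec,
                                                      quiet_warnings):
        cohort = datagen.simulate_cohort(simple_cure_spec)
        design = build_simple_design(cohort)
        fit = em_fit(design)
        summ = strata_summary(fit, {"none": np.zeros(design.n, dtype=bool)})
        row = summ.table.iloc[0]
        assert row["n"] == 0
        assert not row["median_defined"]
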