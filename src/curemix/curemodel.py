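"""Semiparametric mixture cure model estimated by EM.

The population survival is the two-component mixture

    S(t | x, z) = 1 - pi(z) + pi(z) * Su(t | x)

where pi(z) = expit(b'z) is the logistic *incidence* model (probability
of being uncured, i.e. susceptible to the event) and Su(t | x) is a Cox
proportional-hazards *latency* model with a nonparametric (Breslow)
baseline for the uncured.  Estimation alternates:

* E-step: posterior probability w_i of being uncured, given survival to
  the censoring time (w_i = 1 for observed events);
* M-step incidence: weighted logistic fit with fractional responses w;
* M-step latency: weighted Cox fit in which censored subjects enter the
  risk sets with weight w_i, followed by the zero-tail constraint
  (baseline survival forced to 0 beyond the last event time) that makes
  the cure fraction identifiable.

The observed-data log-likelihood is computed under the discrete-baseline
convention that matches the Breslow profile exactly, so the EM trace is
monotone up to numerical tolerance.

Inference is by nonparametric case-resampling bootstrap.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .survcore import (
    ConvergenceWarning,
    CoxFit,
    DiscreteBaseline,
    StepSurvival,
    SurvivalSample,
    cox_fit,
)

__all__ = [
    "CureDesign",
    "MixtureCureFit",
    "CureInference",
    "CureSummary",
    "estep_weights",
    "mstep_incidence",
    "mstep_latency",
    "em_fit",
    "observed_loglik",
    "predict_cure_probability",
    "median_uncured_time",
    "predict_marginal_survival",
    "uncured_survival",
    "mean_marginal_survival",
    "bootstrap_inference",
    "strata_summary",
    "coefficient_report",
]

_LOGIT_CAP = 20.0


# ---------------------------------------------------------------------------
# Design container
# ---------------------------------------------------------------------------

@dataclass
class CureDesign:
    """Incidence design z (with intercept), latency design x (no intercept),
    and the right-censored sample they describe."""

    z: np.ndarray
    x: np.ndarray
    sample: SurvivalSample
    z_names: list[str] = field(default_factory=list)
    x_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim == 1:
            self.x = self.x[:, None]
        if self.x.size == 0:
            self.x = self.x.reshape(self.sample.n, 0)
        n = self.sample.n
        if self.z.shape[0] != n or self.x.shape[0] != n:
            raise ValueError("design row counts must match the sample size")
        intercept_cols = [
            j for j in range(self.z.shape[1]) if np.all(self.z[:, j] == 1.0)
        ]
        if len(intercept_cols) != 1:
            raise ValueError("incidence design must contain exactly one intercept column")
        if not self.z_names:
            self.z_names = ["intercept"] + [f"z{j}" for j in range(1, self.z.shape[1])]
        if not self.x_names:
            self.x_names = [f"x{j}" for j in range(self.x.shape[1])]

    @property
    def n(self) -> int:
        return self.sample.n

    @classmethod
    def build(
        cls,
        frame: pd.DataFrame,
        incidence: list[str],
        latency: list[str],
        time_col: str = "time_years",
        event_col: str = "event_metastasis",
    ) -> "CureDesign":
        """Assemble a design from named columns; an intercept is prepended
        to the incidence block."""
        missing = [c for c in list(incidence) + list(latency) + [time_col, event_col]
                   if c not in frame.columns]
        if missing:
            raise KeyError(f"columns not in frame: {missing}")
        n = len(frame)
        z = np.column_stack(
            [np.ones(n)] + [frame[c].to_numpy(dtype=float) for c in incidence]
        )
        x = (
            np.column_stack([frame[c].to_numpy(dtype=float) for c in latency])
            if latency
            else np.zeros((n, 0))
        )
        sample = SurvivalSample(
            frame[time_col].to_numpy(dtype=float), frame[event_col].to_numpy()
        )
        return cls(z, x, sample, ["intercept"] + list(incidence), list(latency))

    def subset(self, idx) -> "CureDesign":
        return CureDesign(
            self.z[idx], self.x[idx], self.sample.subset(idx),
            list(self.z_names), list(self.x_names),
        )


# ---------------------------------------------------------------------------
# E-step and M-steps
# ---------------------------------------------------------------------------

def estep_weights(b, beta, baseline: DiscreteBaseline, design: CureDesign) -> np.ndarray:
    """Posterior probability of being uncured.

    Events get w = 1.  A subject censored at t gets
    w = pi * Su(t|x) / (1 - pi + pi * Su(t|x)) with
    Su(t|x) = exp(-Lambda0(t) * exp(beta'x)).  A zero denominator (pi = 1
    while Su = 0, a contradictory configuration) is guarded to w = 0.
    """
    b = np.asarray(b, dtype=float)
    beta = np.asarray(beta, dtype=float)
    pi = expit(design.z @ b)
    eta = design.x @ beta if design.x.shape[1] else np.zeros(design.n)
    ch = baseline.cumhaz_at(design.sample.times)
    su = np.exp(-np.minimum(ch * np.exp(np.clip(eta, -700, 700)), 745.0))
    su = np.where(np.isinf(ch), 0.0, su)
    num = pi * su
    den = 1.0 - pi + num
    w = np.where(den > 1e-300, num / np.maximum(den, 1e-300), 0.0)
    return np.where(design.sample.events == 1, 1.0, w)


def _logistic_newton(Z, y, ridge=0.0, b0=None, tol=1e-10, max_iter=100,
                     intercept_idx=0):
    """Newton maximizer of the (possibly ridge-penalized) Bernoulli
    log-likelihood with fractional responses y in [0, 1]."""
    n, q = Z.shape
    pen = np.full(q, ridge)
    pen[intercept_idx] = 0.0  # intercept never penalized
    b = np.zeros(q) if b0 is None else np.asarray(b0, dtype=float).copy()

    def pll(bv):
        p = expit(Z @ bv)
        p = np.clip(p, 1e-300, 1 - 1e-16)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
                     - 0.5 * np.sum(pen * bv**2))

    ll = pll(b)
    converged = False
    for _ in range(max_iter):
        p = expit(Z @ b)
        g = Z.T @ (y - p) - pen * b
        if np.linalg.norm(g) < tol * (1.0 + n):
            converged = True
            break
        wdiag = np.maximum(p * (1 - p), 1e-12)
        H = (Z * wdiag[:, None]).T @ Z + np.diag(pen)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        scale = 1.0
        for _ in range(40):
            cand = b + scale * step
            ll_new = pll(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        b = cand
        ll = ll_new
        if np.max(np.abs(b)) > _LOGIT_CAP and ridge == 0.0:
            return b, False
    return b, converged


def mstep_incidence(design: CureDesign, weights, *, b0=None) -> np.ndarray:
    """Maximize the weighted Bernoulli likelihood with fractional responses.

    Degenerate responses (all ~0 or all ~1) pin the fit at the logit cap;
    separation triggers a ridge (1e-4) refit with a warning.
    """
    w = np.asarray(weights, dtype=float)
    if np.any((w < -1e-12) | (w > 1 + 1e-12)):
        raise ValueError("weights must lie in [0, 1]")
    w = np.clip(w, 0.0, 1.0)
    q = design.z.shape[1]
    intercept_idx = next(
        j for j in range(q) if np.all(design.z[:, j] == 1.0)
    )
    if np.all(w >= 1 - 1e-12) or np.all(w <= 1e-12):
        b = np.zeros(q)
        b[intercept_idx] = _LOGIT_CAP if w.mean() > 0.5 else -_LOGIT_CAP
        warnings.warn(
            "degenerate incidence responses; intercept capped", ConvergenceWarning
        )
        return b
    b, ok = _logistic_newton(design.z, w, b0=b0, intercept_idx=intercept_idx)
    if not ok or np.max(np.abs(b)) > _LOGIT_CAP:
        warnings.warn(
            "separation in incidence model; refitting with ridge 1e-4",
            ConvergenceWarning,
        )
        b, _ = _logistic_newton(
            design.z, w, ridge=1e-4, b0=None, intercept_idx=intercept_idx
        )
    return b


def mstep_latency(
    design: CureDesign, weights, *, beta0=None
) -> tuple[np.ndarray, DiscreteBaseline, CoxFit]:
    """Weighted Cox fit with censored subjects carrying weight w in risk
    sets, followed by the zero-tail constraint on the Breslow baseline."""
    w = np.asarray(weights, dtype=float)
    sample = SurvivalSample(design.sample.times, design.sample.events, w)
    fit = cox_fit(sample, design.x, initial=beta0)
    baseline = DiscreteBaseline(
        fit.baseline_hazard.times, fit.baseline_hazard.jumps, zero_tail=True
    )
    return fit.beta, baseline, fit


def observed_loglik(b, beta, baseline: DiscreteBaseline, design: CureDesign) -> float:
    """Observed-data log-likelihood of the mixture under the discrete
    Breslow convention.

    Events contribute log pi + log dLambda0(t) + beta'x - Lambda0(t) e^{beta'x}
    (the survival factor includes the jump at the event time, matching the
    complete-data likelihood the M-steps maximize); censored subjects
    contribute log(1 - pi + pi * Su(t|x)).
    """
    b = np.asarray(b, dtype=float)
    beta = np.asarray(beta, dtype=float)
    t = design.sample.times
    ev = design.sample.events == 1
    pi = np.clip(expit(design.z @ b), 1e-12, 1 - 1e-12)
    eta = design.x @ beta if design.x.shape[1] else np.zeros(design.n)
    ehr = np.exp(np.clip(eta, -700, 700))
    ch = baseline.cumhaz_at(t)
    su = np.where(np.isinf(ch), 0.0, np.exp(-np.minimum(np.where(np.isinf(ch), 0, ch) * ehr, 745.0)))
    ll = 0.0
    if ev.any():
        jumps = baseline.jump_at(t[ev])
        ch_ev = ch[ev]
        ll += float(
            np.sum(
                np.log(pi[ev])
                + np.log(np.maximum(jumps, 1e-300))
                + eta[ev]
                - ch_ev * ehr[ev]
            )
        )
    if (~ev).any():
        mix = 1.0 - pi[~ev] + pi[~ev] * su[~ev]
        ll += float(np.sum(np.log(np.maximum(mix, 1e-300))))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite observed-data log-likelihood")
    return ll


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class MixtureCureFit:
    """Fitted mixture cure model."""

    b: np.ndarray | None
    beta: np.ndarray
    baseline: DiscreteBaseline
    w: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    design: CureDesign
    pi_fixed: float | None = None

    @property
    def S0(self) -> StepSurvival:
        """Baseline latency survival with the zero tail."""
        return self.baseline.to_step_survival()

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def pi(self, z_new=None) -> np.ndarray:
        """Probability of being uncured, pi(z)."""
        if self.pi_fixed is not None:
            n = self.design.n if z_new is None else np.atleast_2d(z_new).shape[0]
            return np.full(n, self.pi_fixed)
        z = self.design.z if z_new is None else np.atleast_2d(np.asarray(z_new, float))
        return expit(z @ self.b)

    def to_json_dict(self) -> dict:
        return {
            "incidence": dict(zip(self.design.z_names,
                                  [] if self.b is None else self.b.tolist())),
            "latency": dict(zip(self.design.x_names, self.beta.tolist())),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "loglik": self.loglik,
            "n": int(self.design.n),
            "n_events": int(self.design.sample.n_events),
        }

    def save(self, json_path, baseline_csv_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)
        if baseline_csv_path is not None:
            self.S0.to_csv(baseline_csv_path)


def em_fit(
    design: CureDesign,
    *,
    init: tuple | None = None,
    tol: float = 1e-7,
    max_iter: int = 500,
    pi_fixed: float | None = None,
) -> MixtureCureFit:
    """EM estimation of the semiparametric mixture cure model.

    Alternates E-step / incidence M-step / latency M-step until the
    observed-data log-likelihood changes by less than ``tol`` or
    ``max_iter`` is reached (the fit is then returned with
    ``converged=False``).  ``pi_fixed=1.0`` forces every subject uncured,
    reducing the model to an ordinary Cox fit.

    Warns when no censored subject lies beyond the last event time (the
    Kaplan-Meier plateau that anchors the cure fraction is then empty).
    """
    sample = design.sample
    if sample.n_events < 1:
        raise ValueError("mixture cure model requires at least one event")
    ev = sample.events == 1
    if ev.all() or (pi_fixed is None and sample.times[~ev].max(initial=-np.inf)
                    <= sample.times[ev].max()):
        warnings.warn(
            "no censored subject beyond the last event time; the cure "
            "fraction is weakly identified",
            UserWarning,
        )

    # Initialization: logistic fit of the event flag; Cox fit on all subjects.
    if init is not None:
        b, beta, baseline = init
        b = None if b is None else np.asarray(b, dtype=float)
        beta = np.asarray(beta, dtype=float)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            b = (None if pi_fixed is not None
                 else mstep_incidence(design, sample.events.astype(float)))
            beta, baseline, _ = mstep_latency(design, np.ones(design.n))
    if init is not None and init[2] is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, baseline, _ = mstep_latency(design, np.ones(design.n), beta0=beta)

    def _ll(bv, betav, basev):
        b_eff = _fixed_b(design, pi_fixed) if pi_fixed is not None else bv
        return observed_loglik(b_eff, betav, basev, design)

    trace = [_ll(b, beta, baseline)]
    w = np.ones(design.n)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if pi_fixed is not None:
            if pi_fixed >= 1.0:
                w = np.ones(design.n)
            else:
                w = estep_weights(_fixed_b(design, pi_fixed), beta, baseline, design)
        else:
            w = estep_weights(b, beta, baseline, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            if pi_fixed is None:
                b = mstep_incidence(design, w, b0=b)
            beta, baseline, _ = mstep_latency(design, w, beta0=beta)
        try:
            ll = _ll(b, beta, baseline)
        except FloatingPointError as err:
            raise RuntimeError(
                f"NaN in observed-data log-likelihood at EM iteration {n_iter}; "
                f"b={b}, beta={beta}"
            ) from err
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("EM reached max_iter without converging", ConvergenceWarning)
    return MixtureCureFit(
        b=b,
        beta=beta,
        baseline=baseline,
        w=w,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
        design=design,
        pi_fixed=pi_fixed,
    )


def _fixed_b(design: CureDesign, pi_fixed: float) -> np.ndarray:
    """Incidence coefficient vector realizing a constant pi."""
    q = design.z.shape[1]
    j = next(k for k in range(q) if np.all(design.z[:, k] == 1.0))
    b = np.zeros(q)
    if pi_fixed >= 1.0:
        b[j] = _LOGIT_CAP
    elif pi_fixed <= 0.0:
        b[j] = -_LOGIT_CAP
    else:
        b[j] = np.log(pi_fixed / (1.0 - pi_fixed))
    return b


# ---------------------------------------------------------------------------
# Post-estimation summaries
# ---------------------------------------------------------------------------

def predict_cure_probability(fit: MixtureCureFit, z_new=None) -> np.ndarray:
    """Per-subject cure probability 1 - pi(z)."""
    return 1.0 - fit.pi(z_new)


def uncured_survival(fit: MixtureCureFit, x_row=None) -> StepSurvival:
    """Conditional survival of the uncured, Su(t|x) = S0(t)^exp(beta'x)."""
    base = fit.baseline
    eta = 0.0
    if x_row is not None and fit.beta.size:
        eta = float(np.asarray(x_row, dtype=float) @ fit.beta)
    vals = np.exp(-np.minimum(base.cumhaz * np.exp(eta), 745.0))
    knots, values = base.times, vals
    if base.zero_tail and knots.size:
        knots = np.append(knots, np.nextafter(knots[-1], np.inf))
        values = np.append(values, 0.0)
    return StepSurvival(knots, values)


def median_uncured_time(fit: MixtureCureFit, x_new=None) -> float:
    """Smallest knot t with Su(t|x) <= 0.5; NaN when never crossed
    (undefined median, explicit sentinel)."""
    su = uncured_survival(fit, x_new)
    below = np.nonzero(su.values <= 0.5)[0]
    if below.size == 0:
        return float("nan")
    return float(su.knot_times[below[0]])


def predict_marginal_survival(fit: MixtureCureFit, z_new, x_new) -> StepSurvival:
    """Individualized marginal curve S(t|x,z) = 1 - pi + pi * Su(t|x);
    the curve floors at the cure probability 1 - pi(z)."""
    pi = float(fit.pi(np.atleast_2d(z_new))[0])
    su = uncured_survival(fit, x_new)
    return StepSurvival(su.knot_times, 1.0 - pi + pi * su.values)


def mean_marginal_survival(fit: MixtureCureFit, design: CureDesign | None = None) -> StepSurvival:
    """Pointwise mean of the individualized marginal curves over a cohort
    (the ensemble summary curve)."""
    d = design if design is not None else fit.design
    pi = fit.pi(d.z)
    eta = d.x @ fit.beta if d.x.shape[1] else np.zeros(d.n)
    base = fit.baseline
    su = np.exp(-np.minimum(np.outer(np.exp(np.clip(eta, -700, 700)), base.cumhaz), 745.0))
    mix = (1.0 - pi)[:, None] + pi[:, None] * su
    knots, values = base.times, mix.mean(axis=0)
    if base.zero_tail and knots.size:
        knots = np.append(knots, np.nextafter(knots[-1], np.inf))
        values = np.append(values, float(np.mean(1.0 - pi)))
    return StepSurvival(knots, values)


def _stratum_median(fit: MixtureCureFit, mask: np.ndarray) -> float:
    """Median of the stratum-mean uncured survival curve (NaN if never <= 0.5)."""
    if mask.sum() == 0:
        return float("nan")
    eta = fit.design.x[mask] @ fit.beta if fit.beta.size else np.zeros(int(mask.sum()))
    base = fit.baseline
    su = np.exp(-np.minimum(np.outer(np.exp(np.clip(eta, -700, 700)), base.cumhaz), 745.0))
    mean_su = su.mean(axis=0)
    below = np.nonzero(mean_su <= 0.5)[0]
    if below.size == 0:
        return float("nan")
    return float(base.times[below[0]])


# ---------------------------------------------------------------------------
# Bootstrap inference
# ---------------------------------------------------------------------------

@dataclass
class CureInference:
    """Case-resampling bootstrap inference for a mixture cure fit."""

    fit: MixtureCureFit
    b_se: np.ndarray
    beta_se: np.ndarray
    b_ci: np.ndarray        # (q, 2) percentile CIs
    beta_ci: np.ndarray
    b_p: np.ndarray         # two-sided Wald p-values
    beta_p: np.ndarray
    mean_cure: float
    mean_cure_ci: tuple[float, float]
    n_replicates: int
    n_failed: int
    b_reps: np.ndarray
    beta_reps: np.ndarray
    summaries: list

    def incidence_table(self) -> pd.DataFrame:
        """Incidence block on the odds-ratio scale (OR of being uncured)."""
        b = self.fit.b
        return pd.DataFrame({
            "term": self.fit.design.z_names,
            "OR": np.exp(b),
            "SD": self.b_se,
            "ci_low": np.exp(self.b_ci[:, 0]),
            "ci_high": np.exp(self.b_ci[:, 1]),
            "p_value": self.b_p,
        })

    def latency_table(self) -> pd.DataFrame:
        """Latency block on the hazard-ratio scale."""
        return pd.DataFrame({
            "term": self.fit.design.x_names,
            "HR": np.exp(self.fit.beta),
            "SD": self.beta_se,
            "ci_low": np.exp(self.beta_ci[:, 0]),
            "ci_high": np.exp(self.beta_ci[:, 1]),
            "p_value": self.beta_p,
        })


def bootstrap_inference(
    design: CureDesign,
    B: int = 500,
    seed: int | None = None,
    *,
    summary_fn=None,
    em_kwargs: dict | None = None,
    fit: MixtureCureFit | None = None,
) -> CureInference:
    """Nonparametric case-resampling bootstrap around ``em_fit``.

    SE = SD of replicate coefficients; 95% CIs are percentile; Wald
    p-values compare estimate/SE with the standard normal.  Replicates
    that fail to converge are dropped and counted; more than 20% failures
    attaches a warning.  ``summary_fn(fit, idx)`` may collect extra
    per-replicate summaries (used for stratum CIs).
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    em_kwargs = dict(em_kwargs or {})
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fit is None:
            fit = em_fit(design, **em_kwargs)
    n = design.n
    b_reps, beta_reps, cure_reps, summaries = [], [], [], []
    n_failed = 0
    init = (fit.b, fit.beta, None)
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sub = design.subset(idx)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = em_fit(sub, init=init, **em_kwargs)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not rep.converged:
            n_failed += 1
            continue
        b_reps.append(rep.b)
        beta_reps.append(rep.beta)
        cure_reps.append(float(np.mean(predict_cure_probability(rep))))
        if summary_fn is not None:
            summaries.append(summary_fn(rep, idx))
    if n_failed > 0.2 * B:
        warnings.warn(
            f"{n_failed}/{B} bootstrap replicates failed to converge",
            ConvergenceWarning,
        )
    b_arr = np.asarray(b_reps, dtype=float)
    beta_arr = (np.asarray(beta_reps, dtype=float)
                if beta_reps else np.zeros((0, fit.beta.size)))
    if b_arr.size == 0:
        b_arr = np.zeros((0, design.z.shape[1]))

    def _stats(reps, est):
        if reps.shape[0] < 2:
            q = est.size
            return (np.full(q, np.nan), np.full((q, 2), np.nan), np.full(q, np.nan))
        se = reps.std(axis=0, ddof=1)
        ci = np.percentile(reps, [2.5, 97.5], axis=0).T
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = np.where(se > 0, est / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(zval))
        return se, ci, p

    b_se, b_ci, b_p = _stats(b_arr, fit.b if fit.b is not None else np.zeros(0))
    beta_se, beta_ci, beta_p = _stats(beta_arr, fit.beta)
    cure_arr = np.asarray(cure_reps, dtype=float)
    mean_cure = float(np.mean(predict_cure_probability(fit)))
    if cure_arr.size >= 2:
        mean_cure_ci = tuple(np.percentile(cure_arr, [2.5, 97.5]))
    else:
        mean_cure_ci = (float("nan"), float("nan"))
    return CureInference(
        fit=fit,
        b_se=b_se, beta_se=beta_se,
        b_ci=b_ci, beta_ci=beta_ci,
        b_p=b_p, beta_p=beta_p,
        mean_cure=mean_cure,
        mean_cure_ci=(float(mean_cure_ci[0]), float(mean_cure_ci[1])),
        n_replicates=int(b_arr.shape[0]),
        n_failed=n_failed,
        b_reps=b_arr, beta_reps=beta_arr,
        summaries=summaries,
    )


def coefficient_report(inference: CureInference) -> dict:
    """Two-block report: latency HRs and incidence ORs with bootstrap SDs,
    percentile CIs and Wald p-values."""
    return {
        "latency_model": inference.latency_table().to_dict(orient="records"),
        "incidence_model": inference.incidence_table().to_dict(orient="records"),
        "mean_cure_probability_pct": 100.0 * inference.mean_cure,
        "mean_cure_probability_ci_pct": [100.0 * c for c in inference.mean_cure_ci],
        "n_bootstrap": inference.n_replicates,
        "n_failed": inference.n_failed,
    }


# ---------------------------------------------------------------------------
# Stratified summaries
# ---------------------------------------------------------------------------

@dataclass
class CureSummary:
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def strata_summary(
    fit: MixtureCureFit,
    strata: dict[str, np.ndarray],
    *,
    B: int = 0,
    seed: int | None = None,
    em_kwargs: dict | None = None,
) -> CureSummary:
    """Per-stratum mean cure probability (x100%) and median uncured event
    time, with optional bootstrap percentile CIs (B > 0).

    Empty strata are reported with n=0 and no estimates; a median that the
    uncured curve never reaches is the NaN sentinel with
    ``median_defined=False``.
    """
    masks = {k: np.asarray(v, dtype=bool) for k, v in strata.items()}
    for k, m in masks.items():
        if m.shape != (fit.design.n,):
            raise ValueError(f"stratum mask {k!r} must match the cohort length")

    def _point(f: MixtureCureFit, idx=None):
        out = {}
        cure = predict_cure_probability(f)
        for k, m in masks.items():
            mm = m if idx is None else m[idx]
            if mm.sum() == 0:
                out[k] = (np.nan, np.nan)
                continue
            out[k] = (100.0 * float(cure[mm].mean()), _stratum_median(f, mm))
        return out

    point = _point(fit)
    reps = []
    if B > 0:
        inf = bootstrap_inference(
            fit.design, B=max(B, 50), seed=seed,
            summary_fn=lambda f, idx: _point(f, idx),
            em_kwargs=em_kwargs, fit=fit,
        )
        reps = inf.summaries

    rows = []
    for k, m in masks.items():
        n_k = int(m.sum())
        cure_pct, med = point[k]
        row = {
            "stratum": k,
            "n": n_k,
            "cure_pct": cure_pct if n_k else np.nan,
            "median_years": med if n_k else np.nan,
            "median_defined": bool(n_k and np.isfinite(med)),
        }
        if reps:
            c_reps = np.array([r[k][0] for r in reps], dtype=float)
            m_reps = np.array([r[k][1] for r in reps], dtype=float)
            c_reps = c_reps[np.isfinite(c_reps)]
            m_reps = m_reps[np.isfinite(m_reps)]
            row["cure_ci_low"], row["cure_ci_high"] = (
                tuple(np.percentile(c_reps, [2.5, 97.5])) if c_reps.size >= 2
                else (np.nan, np.nan)
            )
            row["median_ci_low"], row["median_ci_high"] = (
                tuple(np.percentile(m_reps, [2.5, 97.5])) if m_reps.size >= 2
                else (np.nan, np.nan)
            )
        rows.append(row)
    return CureSummary(pd.DataFrame(rows))
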