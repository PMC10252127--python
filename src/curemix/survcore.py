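"""Classical right-censored survival machinery.

Weighted Kaplan-Meier with Greenwood variance, the two-sample log-rank
test, and a weighted Cox proportional-hazards fit with Breslow tie
handling and Breslow baseline.  Weights enter risk sets and event sums
multiplicatively (fractional subjects), which is exactly what the
mixture-cure EM latency M-step requires.

Conventions
-----------
* At tied times, events precede censorings: a subject censored at t is
  still at risk at t.
* The Breslow baseline increment at event time t_k is D_k / S0_k with
  weighted event mass D_k and weighted risk sum S0_k; the baseline is
  therefore invariant under a common rescaling of all weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalSample",
    "StepSurvival",
    "DiscreteBaseline",
    "CoxFit",
    "LogrankResult",
    "km_estimate",
    "survival_at",
    "logrank_test",
    "cox_fit",
    "partial_likelihood_parts",
    "ConvergenceWarning",
]

_COEF_CAP = 40.0  # |beta| beyond this is treated as monotone likelihood


class ConvergenceWarning(UserWarning):
    """Emitted when an iterative fit stops short of its tolerance."""


@dataclass
class SurvivalSample:
    """Right-censored sample: times (years), 0/1 event flags, optional weights."""

    times: np.ndarray
    events: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if np.any(self.times < 0) or not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite and nonnegative")
        ev = np.asarray(self.events, dtype=float)
        if not np.all((ev == 0) | (ev == 1)):
            raise ValueError("events must be 0/1")
        self.events = ev.astype(int)
        if self.weights is None:
            self.weights = np.ones_like(self.times)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.times.shape:
                raise ValueError("weights must match times in length")
            if np.any(self.weights < 0) or not np.all(np.isfinite(self.weights)):
                raise ValueError("weights must be finite and nonnegative")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def subset(self, idx) -> "SurvivalSample":
        return SurvivalSample(self.times[idx], self.events[idx], self.weights[idx])


@dataclass
class StepSurvival:
    """Right-continuous step survival function.

    ``knot_times`` are the (strictly increasing) times at which the value
    drops; the value at 0- is 1.  ``values[k]`` is the survival *at and
    after* ``knot_times[k]`` (until the next knot).
    """

    knot_times: np.ndarray
    values: np.ndarray
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.knot_times = np.asarray(self.knot_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knot_times.shape != self.values.shape:
            raise ValueError("knot_times and values must have equal length")
        if self.knot_times.size and np.any(np.diff(self.knot_times) <= 0):
            raise ValueError("knot_times must be strictly increasing")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if self.values.size and np.any(np.diff(self.values) > 1e-12):
            raise ValueError("survival values must be nonincreasing")
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)
            if self.variance.shape != self.values.shape:
                raise ValueError("variance must match values in length")

    def at(self, t):
        """Right-continuous evaluation; 1 before the first knot, last value after the last."""
        t_arr = np.asarray(t, dtype=float)
        if self.values.size == 0:
            out = np.ones_like(t_arr)
        else:
            idx = np.searchsorted(self.knot_times, t_arr, side="right") - 1
            out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def variance_at(self, t):
        if self.variance is None:
            raise ValueError("curve carries no variance")
        t_arr = np.asarray(t, dtype=float)
        if self.values.size == 0:
            out = np.zeros_like(t_arr)
        else:
            idx = np.searchsorted(self.knot_times, t_arr, side="right") - 1
            out = np.where(idx >= 0, self.variance[np.clip(idx, 0, None)], 0.0)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.knot_times, "survival": self.values}
        if self.variance is not None:
            cols["variance"] = self.variance
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StepSurvival":
        df = pd.read_csv(path)
        var = df["variance"].to_numpy() if "variance" in df.columns else None
        return cls(df["time"].to_numpy(), df["survival"].to_numpy(), var)


def survival_at(curve: StepSurvival, t) -> float:
    """Evaluate a step survival curve at time ``t >= 0`` (right-continuous)."""
    if np.any(np.asarray(t, dtype=float) < 0):
        raise ValueError("t must be nonnegative")
    return curve.at(t)


@dataclass
class DiscreteBaseline:
    """Discrete baseline hazard with masses ``jumps`` at event ``times``.

    ``zero_tail=True`` sets the cumulative hazard to +inf strictly after
    the last event time (survival 0 beyond it) -- the identifiability
    constraint of the semiparametric cure model.
    """

    times: np.ndarray
    jumps: np.ndarray
    zero_tail: bool = False
    cumhaz: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.jumps = np.asarray(self.jumps, dtype=float)
        if self.times.shape != self.jumps.shape:
            raise ValueError("times and jumps must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.jumps < 0):
            raise ValueError("hazard jumps must be nonnegative")
        self.cumhaz = np.cumsum(self.jumps)

    def cumhaz_at(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            out = np.zeros_like(t_arr)
        else:
            idx = np.searchsorted(self.times, t_arr, side="right") - 1
            out = np.where(idx >= 0, self.cumhaz[np.clip(idx, 0, None)], 0.0)
            if self.zero_tail:
                out = np.where(t_arr > self.times[-1], np.inf, out)
        return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def surv_at(self, t):
        ch = self.cumhaz_at(t)
        return np.exp(-ch) if not np.isscalar(ch) else float(np.exp(-ch))

    def jump_at(self, t):
        """Hazard mass at times that are exact knots (0 elsewhere)."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            out = np.zeros_like(t_arr)
            return (float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0
                    else out)
        idx = np.searchsorted(self.times, t_arr, side="left")
        idx_c = np.clip(idx, 0, max(self.times.size - 1, 0))
        hit = (idx < self.times.size) & np.isclose(
            self.times[idx_c], t_arr, rtol=0, atol=0
        )
        out = np.where(hit, self.jumps[idx_c], 0.0)
        return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def to_step_survival(self) -> StepSurvival:
        """Lossless step-survival view; the zero tail becomes a final knot
        immediately after the last event time."""
        if self.times.size == 0:
            return StepSurvival(np.array([]), np.array([]))
        knots = self.times
        vals = np.exp(-self.cumhaz)
        if self.zero_tail:
            knots = np.append(knots, np.nextafter(knots[-1], np.inf))
            vals = np.append(vals, 0.0)
        return StepSurvival(knots, vals)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def _risk_event_sums(sample: SurvivalSample):
    """Weighted at-risk and event mass at each unique event time."""
    order = np.argsort(sample.times, kind="stable")
    ts, ws, es = sample.times[order], sample.weights[order], sample.events[order]
    event_times = np.unique(ts[es == 1])
    if event_times.size == 0:
        return event_times, np.array([]), np.array([])
    rev_cum = np.concatenate([np.cumsum(ws[::-1])[::-1], [0.0]])
    first_idx = np.searchsorted(ts, event_times, side="left")
    n_at_risk = rev_cum[first_idx]
    ew = np.where(es == 1, ws, 0.0)
    cum_ew = np.concatenate([[0.0], np.cumsum(ew)])
    last_idx = np.searchsorted(ts, event_times, side="right")
    d = cum_ew[last_idx] - cum_ew[first_idx]
    return event_times, n_at_risk, d


def km_estimate(sample: SurvivalSample) -> StepSurvival:
    """Product-limit estimator with Greenwood variance, supporting weights.

    Knots are placed at the unique event times; the curve equals 1 (with
    variance 0) before the first event.
    """
    if sample.n == 0:
        raise ValueError("sample must contain at least one subject")
    event_times, n_at_risk, d = _risk_event_sums(sample)
    if event_times.size == 0:
        return StepSurvival(np.array([]), np.array([]), np.array([]))
    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)
    denom = n_at_risk * (n_at_risk - d)
    g = np.where(denom > 0, d / np.where(denom > 0, denom, 1.0), 0.0)
    var = surv**2 * np.cumsum(g)
    return StepSurvival(event_times, surv, var)


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    observed_minus_expected: float
    variance: float


def logrank_test(sample_a: SurvivalSample, sample_b: SurvivalSample) -> LogrankResult:
    """Two-sample log-rank test (chi-square on 1 df, two-sided p).

    Uses the hypergeometric variance at each pooled event time.  If the
    variance sums to 0 (e.g. no events), the statistic is 0 and p = 1.
    """
    if sample_a.n == 0 or sample_b.n == 0:
        raise ValueError("both samples must be nonempty")
    times = np.concatenate([sample_a.times, sample_b.times])
    events = np.concatenate([sample_a.events, sample_b.events])
    weights = np.concatenate([sample_a.weights, sample_b.weights])
    group = np.concatenate([np.zeros(sample_a.n), np.ones(sample_b.n)])

    event_times = np.unique(times[events == 1])
    o_minus_e = 0.0
    var = 0.0
    for tk in event_times:
        at_risk = times >= tk
        n1 = weights[at_risk & (group == 0)].sum()
        n2 = weights[at_risk & (group == 1)].sum()
        nk = n1 + n2
        ev_here = at_risk & (events == 1) & (times == tk)
        d1 = weights[ev_here & (group == 0)].sum()
        dk = weights[ev_here].sum()
        if nk <= 0:
            continue
        o_minus_e += d1 - dk * n1 / nk
        if nk > 1:
            var += dk * (n1 / nk) * (n2 / nk) * (nk - dk) / (nk - 1)
    if var <= 0:
        return LogrankResult(0.0, 1.0, float(o_minus_e), 0.0)
    stat = o_minus_e**2 / var
    p = float(stats.chi2.sf(stat, df=1))
    return LogrankResult(float(stat), p, float(o_minus_e), float(var))


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, weighted)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    beta: np.ndarray
    covariance: np.ndarray
    baseline_hazard: DiscreteBaseline
    loglik: float
    n_events: int
    converged: bool
    n_iter: int

    @property
    def baseline(self) -> StepSurvival:
        """Breslow baseline survival exp(-Lambda0(t))."""
        return self.baseline_hazard.to_step_survival()


def _cox_arrays(sample: SurvivalSample, X: np.ndarray):
    order = np.argsort(sample.times, kind="stable")
    ts = sample.times[order]
    ws = sample.weights[order]
    es = sample.events[order]
    Xs = X[order]
    event_times = np.unique(ts[es == 1])
    first_idx = np.searchsorted(ts, event_times, side="left")
    ew = np.where(es == 1, ws, 0.0)
    cum_ew = np.concatenate([[0.0], np.cumsum(ew)])
    last_idx = np.searchsorted(ts, event_times, side="right")
    D = cum_ew[last_idx] - cum_ew[first_idx]
    return ts, ws, es, Xs, event_times, first_idx, D


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def partial_likelihood_parts(sample: SurvivalSample, covariates, beta):
    """Weighted Breslow partial log-likelihood, score and information at ``beta``.

    Exposed so the score-test identity with the log-rank statistic can be
    checked directly.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != sample.n:
        X = X.T
    beta = np.asarray(beta, dtype=float)
    ts, ws, es, Xs, event_times, first_idx, D = _cox_arrays(sample, X)
    eta = Xs @ beta if X.shape[1] else np.zeros(sample.n)
    r = ws * np.exp(np.clip(eta, -700, 700))
    s0 = np.concatenate([_suffix_cumsum(r), [0.0]])[first_idx]
    ll = float(np.sum(ws * es * eta) - np.sum(D * np.log(np.maximum(s0, 1e-300))))
    p = X.shape[1]
    if p == 0:
        return ll, np.zeros(0), np.zeros((0, 0))
    s1 = _suffix_cumsum(r[:, None] * Xs)[first_idx]
    rXX = r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
    s2 = _suffix_cumsum(rXX)[first_idx]
    mean_k = s1 / s0[:, None]
    grad = (ws * es) @ Xs - D @ mean_k
    info = np.einsum("k,kij->ij", D, s2 / s0[:, None, None]) - np.einsum(
        "k,ki,kj->ij", D, mean_k, mean_k
    )
    return ll, grad, info


def cox_fit(
    sample: SurvivalSample,
    covariates,
    *,
    initial=None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Newton-Raphson maximizer of the weighted Breslow partial likelihood.

    Step-halving keeps the partial log-likelihood monotone.  Monotone
    likelihood (separation within risk sets) is flagged: the fit is
    returned non-converged with coefficients capped at +/-40.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.size == 0:
        X = X.reshape(sample.n, 0)
    if X.shape[0] != sample.n:
        raise ValueError("covariate rows must match sample size")
    if sample.n_events < 1:
        raise ValueError("cox_fit requires at least one event")
    active = sample.weights > 0
    for j in range(X.shape[1]):
        if X[active, j].size and np.ptp(X[active, j]) == 0:
            raise ValueError(f"covariate column {j} is constant among subjects at risk")

    p = X.shape[1]
    beta = np.zeros(p) if initial is None else np.asarray(initial, dtype=float).copy()
    ll, grad, info = partial_likelihood_parts(sample, X, beta)
    converged = p == 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving line search
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = partial_likelihood_parts(sample, X, cand)[0]
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = cand
        ll_old = ll
        ll, grad, info = partial_likelihood_parts(sample, X, beta)
        if np.max(np.abs(beta)) > _COEF_CAP:
            warnings.warn(
                "monotone partial likelihood (separation in risk sets); "
                "coefficients capped at +/-40",
                ConvergenceWarning,
            )
            beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
            ll, grad, info = partial_likelihood_parts(sample, X, beta)
            converged = False
            break
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
            converged = True
            break
    else:
        warnings.warn("cox_fit reached max_iter without converging", ConvergenceWarning)

    if p and np.max(np.abs(beta)) > 15.0:
        # likelihood has flattened along a monotone direction
        warnings.warn(
            "monotone partial likelihood (separation in risk sets); "
            "coefficients capped at +/-40",
            ConvergenceWarning,
        )
        beta = np.clip(beta, -_COEF_CAP, _COEF_CAP)
        ll, grad, info = partial_likelihood_parts(sample, X, beta)
        converged = False

    # Breslow baseline at the fitted beta
    ts, ws, es, Xs, event_times, first_idx, D = _cox_arrays(sample, X)
    eta = Xs @ beta if p else np.zeros(sample.n)
    r = ws * np.exp(np.clip(eta, -700, 700))
    s0 = np.concatenate([_suffix_cumsum(r), [0.0]])[first_idx]
    jumps = D / np.maximum(s0, 1e-300)
    baseline = DiscreteBaseline(event_times, jumps)
    if p:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
        cov = (cov + cov.T) / 2
    else:
        cov = np.zeros((0, 0))
    return CoxFit(
        beta=beta,
        covariance=cov,
        baseline_hazard=baseline,
        loglik=ll,
        n_events=sample.n_events,
        converged=converged,
        n_iter=n_iter,
    )
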