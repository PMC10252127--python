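"""Nonparametric test of cure probability at a follow-up horizon.

Under a mixture cure model with sufficient follow-up, the Kaplan-Meier
estimate at a horizon tau is the nonparametric estimator of the
probability of being event-free at tau, whose plateau level estimates
the cure fraction.  The one-sided test of

    H0: cure probability <= c0   vs   H1: cure probability > c0

uses the KM estimate at tau with its Greenwood standard error, by
default on the complementary log-log scale (delta method), which
respects the [0, 1] range.  Small-sample boundaries:

* KM(tau) = 1 (no events by tau): normal theory degenerates; the exact
  binomial bound p = c0^m is used, with m the number at risk at tau.
* c0 = 0: the point null of no cure.  If the largest observation is an
  event there is no terminal censoring plateau and p = 1; otherwise the
  binomial bound degenerates to 0 (any nonempty plateau has null
  probability zero under sufficient follow-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survcore import StepSurvival, SurvivalSample, km_estimate

__all__ = ["CureTestResult", "cure_probability_test", "cure_test_profile"]


@dataclass
class CureTestResult:
    tau: float
    c0: float
    estimate: float
    se: float
    z: float
    p: float
    n_at_risk_at_tau: int
    scale: str


def _n_at_risk(sample: SurvivalSample, tau: float) -> int:
    return int(np.sum(sample.times >= tau))


def cure_probability_test(
    sample: SurvivalSample,
    tau: float,
    c0: float,
    scale: str = "cloglog",
    *,
    km: StepSurvival | None = None,
) -> CureTestResult:
    """One-sided test of H0: cure probability <= c0 at horizon ``tau``."""
    if not 0 <= c0 < 1:
        raise ValueError("c0 must lie in [0, 1)")
    if scale not in ("identity", "cloglog"):
        raise ValueError("scale must be 'identity' or 'cloglog'")
    m = _n_at_risk(sample, tau)
    if m == 0:
        raise ValueError(
            f"no subjects at risk at tau={tau:g}; choose a smaller horizon"
        )
    curve = km if km is not None else km_estimate(sample)
    est = float(curve.at(tau))
    var = float(curve.variance_at(tau)) if curve.variance is not None else 0.0
    se = float(np.sqrt(max(var, 0.0)))

    if c0 == 0.0:
        # Point null of zero cure: plateau-based boundary rule.
        ev_times = sample.times[sample.events == 1]
        if ev_times.size == 0:
            p = 0.0 if m > 0 else 1.0
            return CureTestResult(tau, c0, est, se, np.inf, p, m, scale)
        t_last_event = float(ev_times.max())
        plateau = int(np.sum((sample.events == 0) & (sample.times > t_last_event)))
        p = 1.0 if plateau == 0 else 0.0
        z = -np.inf if plateau == 0 else np.inf
        return CureTestResult(tau, c0, est, se, z, p, m, scale)

    if est >= 1.0 or se == 0.0:
        if est >= 1.0:
            # exact bound: all m subjects at risk at tau are event-free
            p = float(c0**m)
            z = float(stats.norm.isf(min(max(p, 1e-300), 1.0)))
            return CureTestResult(tau, c0, est, se, z, p, m, scale)
        # estimate < 1 with zero SE (degenerate weights); no evidence metric
        z = 0.0 if est == c0 else (np.inf if est > c0 else -np.inf)
        p = float(stats.norm.sf(z)) if np.isfinite(z) else (0.0 if z > 0 else 1.0)
        return CureTestResult(tau, c0, est, se, z, p, m, scale)

    if est <= 0.0:
        return CureTestResult(tau, c0, est, se, -np.inf, 1.0, m, scale)

    if scale == "identity":
        z = (est - c0) / se
    else:
        # theta = log(-log S) is decreasing in S; delta-method SE
        se_theta = se / (est * abs(np.log(est))) if est < 1 else np.inf
        theta_hat = np.log(-np.log(est))
        theta_0 = np.log(-np.log(c0))
        z = (theta_0 - theta_hat) / se_theta
    p = float(stats.norm.sf(z))
    return CureTestResult(tau, c0, est, se, float(z), p, m, scale)


def cure_test_profile(
    sample: SurvivalSample,
    taus=tuple(range(1, 9)),
    c0s=(0.0, 0.7, 0.8),
    scale: str = "cloglog",
) -> pd.DataFrame:
    """Grid of cure tests (one row per (tau, c0)); cells that cannot be
    computed are kept with a reason and NaN results.  No multiplicity
    adjustment is applied."""
    curve = km_estimate(sample)
    rows = []
    for tau in taus:
        for c0 in c0s:
            try:
                r = cure_probability_test(sample, float(tau), float(c0),
                                          scale, km=curve)
                rows.append({
                    "tau": float(tau), "c0": float(c0), "estimate": r.estimate,
                    "se": r.se, "z": r.z, "p": r.p,
                    "n_at_risk": r.n_at_risk_at_tau, "note": "",
                })
            except ValueError as err:
                rows.append({
                    "tau": float(tau), "c0": float(c0), "estimate": np.nan,
                    "se": np.nan, "z": np.nan, "p": np.nan,
                    "n_at_risk": 0, "note": str(err),
                })
    return pd.DataFrame(rows)
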