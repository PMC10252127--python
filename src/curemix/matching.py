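"""Propensity-score matching and balance diagnostics.

The subgroup analysis matches low- vs high-activity radioactive source
(LARS = 1 treated arm) within age strata: a logistic propensity model on
the pre-treatment confounders, then greedy 1:1 nearest-neighbor matching
without replacement on the logit of the propensity score, treated units
processed in descending score order (the historical default of the
matching package the study cites).  Balance is summarized by
standardized mean differences before/after matching, and each matched
stratum is refit with the mixture cure model (LARS in incidence, mean
dose rate in latency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .curemodel import (
    CureDesign,
    MixtureCureFit,
    em_fit,
    predict_cure_probability,
)
from .survcore import ConvergenceWarning

__all__ = [
    "PropensityModel",
    "MatchedSet",
    "StratumResult",
    "fit_propensity",
    "nn_match",
    "balance_table",
    "psm_subgroup_analysis",
]

_SCORE_CLIP = 1e-6


def _design_matrix(frame: pd.DataFrame, confounders: list[str]):
    """Numeric design with one-hot (drop-first) encoding of categoricals;
    constant columns are dropped with a warning."""
    if not confounders:
        return pd.DataFrame(index=frame.index), []
    X = pd.get_dummies(frame[list(confounders)], drop_first=True, dtype=float)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant confounders: {dropped}", UserWarning)
        X = X.drop(columns=dropped)
    return X.astype(float), list(X.columns)


@dataclass
class PropensityModel:
    coefficients: pd.Series
    scores: np.ndarray          # fitted P(treated | confounders), clipped
    treatment: np.ndarray       # 0/1
    ids: np.ndarray
    ridged: bool = False

    @property
    def logits(self) -> np.ndarray:
        return np.log(self.scores / (1.0 - self.scores))


def fit_propensity(
    frame: pd.DataFrame,
    confounders: list[str],
    treatment_col: str = "lars",
    id_col: str = "patient_id",
) -> PropensityModel:
    """Maximum-likelihood logistic model for treatment assignment; falls
    back to a small ridge penalty on separation."""
    y = frame[treatment_col].to_numpy(dtype=float)
    if not np.all(np.isin(y, [0.0, 1.0])):
        raise ValueError(f"{treatment_col} must be binary 0/1")
    X, names = _design_matrix(frame, confounders)
    exog = sm.add_constant(X.to_numpy(dtype=float) if names else
                           np.empty((len(frame), 0)), has_constant="add")
    ridged = False
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        separated = any("separation" in str(w.message).lower() for w in caught)
        params = np.asarray(res.params, dtype=float)
        if (separated or not np.all(np.isfinite(params))
                or np.max(np.abs(params)) > 30):
            raise np.linalg.LinAlgError("separation")
        scores = np.asarray(res.predict(exog), dtype=float)
    except Exception:
        warnings.warn(
            "separation in propensity model; refitting with ridge 1e-4",
            ConvergenceWarning,
        )
        ridged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, exog, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-4, L1_wt=0.0
            )
        params = np.asarray(res.params, dtype=float)
        scores = np.asarray(res.predict(exog), dtype=float)
    scores = np.clip(scores, _SCORE_CLIP, 1 - _SCORE_CLIP)
    ids = (frame[id_col].to_numpy() if id_col in frame.columns
           else np.arange(len(frame)))
    return PropensityModel(
        coefficients=pd.Series(params, index=["(Intercept)"] + names),
        scores=scores,
        treatment=y.astype(int),
        ids=ids,
        ridged=ridged,
    )


@dataclass
class MatchedSet:
    pairs: list[tuple]                    # (treated_id, control_id) per match
    unmatched_treated: list
    unmatched_control: list
    balance: pd.DataFrame | None = None
    caliper: float | None = None
    distances: list[float] = field(default_factory=list)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_ids(self) -> np.ndarray:
        if not self.pairs:
            return np.array([], dtype=object)
        return np.concatenate([[t for t, _ in self.pairs],
                               [c for _, c in self.pairs]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def nn_match(
    model: PropensityModel,
    ratio: int = 1,
    caliper: float | None = None,
) -> MatchedSet:
    """Greedy nearest-neighbor matching without replacement on the logit
    propensity score.

    Treated units are processed in descending score order; ties break by
    ascending subject id (deterministic).  ``caliper`` is in units of the
    SD of the logit score; candidate controls beyond it are discarded
    (possibly yielding fewer pairs, or none).
    """
    if ratio != 1:
        raise NotImplementedError("only 1:1 matching is supported")
    logit = model.logits
    treated = np.nonzero(model.treatment == 1)[0]
    control = np.nonzero(model.treatment == 0)[0]
    if treated.size == 0 or control.size == 0:
        raise ValueError("both arms must be nonempty")
    sd_logit = float(np.std(logit, ddof=1)) if logit.size > 1 else 0.0
    max_dist = np.inf if caliper is None else caliper * sd_logit

    # descending score, ties by ascending id
    t_order = treated[np.lexsort((model.ids[treated], -logit[treated]))]
    avail = control.copy()
    pairs, dists, unmatched_t = [], [], []
    for ti in t_order:
        if avail.size == 0:
            unmatched_t.append(model.ids[ti])
            continue
        d = np.abs(logit[avail] - logit[ti])
        best = d.min()
        if best > max_dist:
            unmatched_t.append(model.ids[ti])
            continue
        cand = avail[np.isclose(d, best, rtol=0, atol=1e-12)]
        ci = cand[np.argmin(model.ids[cand])]  # tie-break by id
        pairs.append((model.ids[ti], model.ids[ci]))
        dists.append(float(np.abs(logit[ci] - logit[ti])))
        avail = avail[avail != ci]
    return MatchedSet(
        pairs=pairs,
        unmatched_treated=unmatched_t,
        unmatched_control=[model.ids[c] for c in avail],
        caliper=caliper,
        distances=dists,
    )


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Standardized mean difference with pooled SD; 0 when both the
    difference and the pooled SD vanish, +/-inf when only the SD does."""
    mt, mc = float(np.mean(x_t)), float(np.mean(x_c))
    vt = float(np.var(x_t, ddof=1)) if x_t.size > 1 else 0.0
    vc = float(np.var(x_c, ddof=1)) if x_c.size > 1 else 0.0
    pooled = np.sqrt((vt + vc) / 2.0)
    diff = mt - mc
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return diff / pooled


def balance_table(
    frame: pd.DataFrame,
    covariates: list[str],
    matched: MatchedSet | None = None,
    treatment_col: str = "lars",
    id_col: str = "patient_id",
) -> pd.DataFrame:
    """Per-covariate standardized mean differences before (and, when a
    matched set is given, after) matching.  Categorical covariates are
    expanded to level indicators (proportions)."""
    X, names = _design_matrix(frame, covariates)
    treat = frame[treatment_col].to_numpy(dtype=float) == 1
    rows = []
    matched_mask = None
    if matched is not None:
        ids = frame[id_col].to_numpy()
        matched_mask = np.isin(ids, matched.matched_ids())
    for name in names:
        x = X[name].to_numpy(dtype=float)
        row = {"covariate": name, "smd_before": _smd(x[treat], x[~treat])}
        if matched_mask is not None:
            mt = matched_mask & treat
            mc = matched_mask & ~treat
            row["smd_after"] = (
                _smd(x[mt], x[mc]) if mt.any() and mc.any() else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


DEFAULT_CONFOUNDERS = ["differentiation", "stage_adv", "mean_dose",
                       "duration_days", "chemo"]


@dataclass
class StratumResult:
    label: str
    matched: MatchedSet
    fit: MixtureCureFit
    balance: pd.DataFrame
    cure_prob_by_arm: dict[str, float]
    incidence_or_lars: float
    latency_hr_dose_rate: float
    n_events: int


def psm_subgroup_analysis(
    encoded: pd.DataFrame,
    age_cut: float = 53.0,
    confounders: list[str] | None = None,
    *,
    min_events: int = 20,
    treatment_col: str = "lars",
    latency_col: str = "mean_dose_rate_std",
    em_kwargs: dict | None = None,
) -> dict:
    """Within each age stratum (<= cut vs > cut): fit the propensity
    model, match LARS vs HARS 1:1, refit the mixture cure model on the
    matched data (LARS in incidence, mean dose rate in latency) and
    report the model-implied cure probability per arm.

    Strata with fewer than ``min_events`` events after matching, or with
    a single arm, are skipped with a reason string instead of a result.
    """
    confounders = DEFAULT_CONFOUNDERS if confounders is None else confounders
    out = {}
    age = encoded["age"].to_numpy(dtype=float)
    for label, mask in (
        (f"age_le_{age_cut:g}", age <= age_cut),
        (f"age_gt_{age_cut:g}", age > age_cut),
    ):
        sub = encoded.loc[mask].reset_index(drop=True)
        arms = sub[treatment_col].nunique()
        if len(sub) == 0 or arms < 2:
            out[label] = f"skipped: stratum has {arms} treatment arm(s)"
            continue
        model = fit_propensity(sub, confounders, treatment_col=treatment_col)
        matched = nn_match(model)
        matched.balance = balance_table(sub, confounders, matched,
                                        treatment_col=treatment_col)
        m_ids = matched.matched_ids()
        mdat = sub[sub["patient_id"].isin(m_ids)].reset_index(drop=True)
        n_events = int(mdat["event_metastasis"].sum())
        if n_events < min_events:
            out[label] = (
                f"skipped: {n_events} events after matching (< {min_events})"
            )
            continue
        design = CureDesign.build(mdat, [treatment_col], [latency_col])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = em_fit(design, **(em_kwargs or {}))
        cure = predict_cure_probability(fit)
        arm = mdat[treatment_col].to_numpy(dtype=float) == 1
        out[label] = StratumResult(
            label=label,
            matched=matched,
            fit=fit,
            balance=matched.balance,
            cure_prob_by_arm={
                "lars": float(cure[arm].mean()),
                "hars": float(cure[~arm].mean()),
            },
            incidence_or_lars=float(np.exp(fit.b[1])),
            latency_hr_dose_rate=float(np.exp(fit.beta[0])) if fit.beta.size
            else float("nan"),
            n_events=n_events,
        )
    return out
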