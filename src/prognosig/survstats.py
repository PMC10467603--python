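"""Survival-analysis primitives used throughout the pipeline.

Kaplan–Meier estimation, multi-group log-rank testing and Cox proportional
hazards fits are delegated to lifelines; ROC analysis to scikit-learn; the
binomial risk-of-recurrence curve to statsmodels.  The maximally selected
log-rank cutpoint — the dichotomization device at the core of the screening
and scoring stages — is implemented in this package (`_logrank`), because no
installed library provides it and because it must be fast enough to run
hundreds of thousands of times inside the beam search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from sklearn.metrics import roc_auc_score, roc_curve

from ._logrank import NoAdmissibleSplitError, SurvivalIndex, scan_cutpoints, two_group_stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutpointResult",
    "CoxFit",
    "ROCResult",
    "RiskCurve",
    "NoAdmissibleSplitError",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "cox_fit",
    "roc_analysis",
    "risk_of_recurrence_curve",
]


def _clean_surv(time, event):
    time = np.asarray(time, dtype=np.float64)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("at least one outcome is required")
    if np.any(time < 0):
        raise ValueError("negative survival time")
    if not np.all(np.isin(np.unique(event), [0, 1])):
        raise ValueError("event must be 0/1")
    return time, event.astype(int)


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored observations only shrink the risk sets; the returned curve is
    evaluated at the distinct observed event times.
    """
    time, event = _clean_surv(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    if len(ev) == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]))
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    return KMCurve(times, surv, at_risk)


@dataclass
class LogRankResult:
    chi2: float
    p: float
    df: int
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(groups) -> LogRankResult:
    """Mantel–Cox log-rank test across ≥2 groups of (time, event) pairs.

    Parameters
    ----------
    groups : sequence of (time, event) array pairs, one per group.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, pair in enumerate(groups):
        t, e = _clean_surv(*pair)
        if t.size == 0:
            raise ValueError(f"group {g} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    time = np.concatenate(times)
    event = np.concatenate(events)
    label = np.concatenate(labels)
    df = len(groups) - 1

    idx = SurvivalIndex(time, event)
    membership = np.stack([label == g for g in range(len(groups))])
    o_minus_e, _, _ = two_group_stats(membership, idx)
    observed = np.array([events[g].sum() for g in range(len(groups))], dtype=float)
    expected = observed - o_minus_e

    if idx.total_events == 0:
        return LogRankResult(0.0, 1.0, df, observed, expected)
    res = multivariate_logrank_test(time, label, event)
    return LogRankResult(float(res.test_statistic), float(res.p_value), df, observed, expected)


@dataclass
class CutpointResult:
    """Maximally selected log-rank cutpoint for a continuous marker."""

    cutpoint: float
    std_statistic: float  # signed z for the high group at the cutpoint
    minprop: float
    chi2: float
    p: float
    n_high: int
    n_low: int

    @property
    def direction(self) -> str:
        """'unfavorable' when high marker values carry worse survival."""
        return "unfavorable" if self.std_statistic > 0 else "favorable"


def optimal_cutpoint(values, time, event, minprop: float = 0.1) -> CutpointResult:
    """Cut-off maximizing the standardized two-group log-rank statistic.

    Scans the midpoints between consecutive sorted unique values whose
    induced split leaves at least ``minprop`` of the samples on both sides;
    exact statistic ties resolve to the smallest cutpoint.
    """
    time, event = _clean_surv(time, event)
    if time.size < 10:
        raise ValueError("optimal_cutpoint requires at least 10 samples")
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must lie in (0, 0.5)")
    idx = SurvivalIndex(time, event)
    res = scan_cutpoints(values, idx, minprop=minprop)
    return CutpointResult(
        cutpoint=res["cutpoint"],
        std_statistic=res["z"],
        minprop=minprop,
        chi2=res["chi2"],
        p=res["p"],
        n_high=res["n_high"],
        n_low=res["n_low"],
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (Efron tie handling)."""

    summary: pd.DataFrame  # index: covariate; columns: coef, hr, ci_lower, ci_upper, p
    converged: bool
    flags: list = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(design: pd.DataFrame, time, event) -> CoxFit:
    """Partial-likelihood Cox regression of (time, event) on `design`.

    Non-convergence, separation or a singular design are reported through
    ``converged``/``flags`` rather than raised, matching how screening-scale
    callers need to keep going past degenerate fits.
    """
    time, event = _clean_surv(time, event)
    design = pd.DataFrame(design)
    if design.shape[0] != time.size:
        raise ValueError("design and outcomes disagree on sample count")
    nunique = design.nunique()
    if (nunique <= 1).any():
        const = list(nunique.index[nunique <= 1])
        raise ValueError(f"constant covariate(s): {const}")
    if event.sum() < design.shape[1]:
        raise ValueError("fewer events than covariates")

    flags = []
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) <= X.shape[1]:
        flags.append("singular design")

    df = design.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="_time", event_col="_event")
        for w in caught:
            if "convergence" in str(w.message).lower() or "collinear" in str(w.message).lower():
                flags.append(str(w.message).splitlines()[0])
        if any("convergence" in f.lower() for f in flags):
            converged = False
    except ConvergenceError as err:
        flags.append(f"ConvergenceError: {err}")
        nan = np.full(design.shape[1], np.nan)
        summary = pd.DataFrame(
            {"coef": nan, "hr": nan, "ci_lower": nan, "ci_upper": nan, "p": nan},
            index=design.columns,
        )
        return CoxFit(summary, converged=False, flags=flags)

    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    summary.index = list(design.columns)
    return CoxFit(summary, converged=converged, flags=flags)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_threshold: float
    chosen_sensitivity: float
    chosen_specificity: float


def roc_analysis(scores, labels) -> ROCResult:
    """ROC curve of a risk score against binary relapse labels.

    AUC equals the pairwise concordance probability (ties count 1/2).  The
    reported operating point maximizes the Youden index (sens + spec - 1);
    ties resolve to the highest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    youden = tpr - fpr
    best = int(np.argmax(youden))  # roc_curve thresholds descend: first max = highest
    return ROCResult(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        chosen_threshold=float(thr[best]),
        chosen_sensitivity=float(tpr[best]),
        chosen_specificity=float(1.0 - fpr[best]),
    )


@dataclass
class RiskCurve:
    """Predicted probability of recurrence by a time horizon vs. score."""

    score_grid: np.ndarray
    risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    slope_p: float
    horizon: float
    n_used: int
    degenerate: bool = False


def risk_of_recurrence_curve(scores, time, event, horizon: float = 120.0) -> RiskCurve:
    """Binomial GLM of event-by-horizon status on the recurrence score.

    Samples censored before the horizon without an event carry no
    information about horizon status and are excluded.  With a single
    distinct score, or with all/none of the usable samples relapsing, the
    fit degenerates to the observed event fraction and is flagged.
    """
    scores = np.asarray(scores, dtype=float)
    time, event = _clean_surv(time, event)
    usable = (event == 1) & (time <= horizon) | (time >= horizon)
    y = ((event == 1) & (time <= horizon)).astype(float)[usable]
    x = scores[usable]
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValueError("no sample is informative at the requested horizon")

    grid = np.unique(x)
    if np.allclose(grid, np.round(grid)):
        grid = np.arange(grid.min(), grid.max() + 1)

    frac = float(y.mean())
    if np.unique(x).size < 2 or frac in (0.0, 1.0):
        flat = np.full(grid.size, frac)
        return RiskCurve(grid, flat, flat.copy(), flat.copy(), 1.0, horizon, n_used, True)

    exog = sm.add_constant(x)
    model = sm.GLM(y, exog, family=sm.families.Binomial())
    fit = model.fit()
    pred = fit.get_prediction(sm.add_constant(grid, has_constant="add"))
    frame = pred.summary_frame(alpha=0.05)
    return RiskCurve(
        score_grid=grid,
        risk=frame["mean"].to_numpy(),
        ci_lower=np.clip(frame["mean_ci_lower"].to_numpy(), 0, 1),
        ci_upper=np.clip(frame["mean_ci_upper"].to_numpy(), 0, 1),
        slope_p=float(fit.pvalues[1]),
        horizon=horizon,
        n_used=n_used,
    )
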