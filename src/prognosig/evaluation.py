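"""Evaluation battery for trained signatures: KM/HR performance reports,
ROC operating points, multivariate Cox tables, combined signature + pT
stratification, and signature-vs-signature comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import Cohort
from .scoring import Signature, classify_high_low, recurrence_scores
from .survstats import KMCurve, cox_fit, km_estimate, logrank_test, roc_analysis

logger = logging.getLogger(__name__)

__all__ = [
    "PerformanceReport",
    "ComparisonReport",
    "StratifiedKMReport",
    "evaluate_signature",
    "multivariate_report",
    "combined_pt_stratification",
    "compare_signatures",
]


@dataclass
class PerformanceReport:
    signature: str
    endpoint: str
    hr: float
    hr_ci: tuple
    hr_p: float
    logrank_chi2: float
    logrank_p: float
    auc: float
    sensitivity: float
    specificity: float
    accuracy: float
    score_cutoff: float
    n_high: int
    n_low: int
    km_high: KMCurve = None
    km_low: KMCurve = None
    roc: object = None  # full ROCResult for curve plotting

    def to_dict(self) -> dict:
        return {
            "signature": self.signature,
            "endpoint": self.endpoint,
            "hr": self.hr,
            "hr_ci_lower": self.hr_ci[0],
            "hr_ci_upper": self.hr_ci[1],
            "hr_p": self.hr_p,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "score_cutoff": self.score_cutoff,
            "n_high": self.n_high,
            "n_low": self.n_low,
        }


def evaluate_signature(
    sig: Signature, cohort: Cohort, endpoint: str = "RFS", minprop: float = 0.1
) -> PerformanceReport:
    """Full performance report of a signature on one cohort.

    The high/low classification is always trained on RFS (the outcome the
    cut-offs were designed for); KM, log-rank and the two-group Cox hazard
    ratio are computed on the requested endpoint.  ROC uses the integer
    scores against relapse-ever labels; sensitivity/specificity/accuracy
    are reported at the Youden-optimal operating point.
    """
    scores = recurrence_scores(sig, cohort, minprop=minprop)
    rfs_t, rfs_e = cohort.survival("RFS")
    labels, cutoff = classify_high_low(scores.to_numpy(), rfs_t, rfs_e, minprop=minprop)
    sig.score_cutoff[cohort.name] = cutoff

    time, event = cohort.survival(endpoint)
    lr = logrank_test(
        [(time[labels], event[labels]), (time[~labels], event[~labels])]
    )
    fit = cox_fit(pd.DataFrame({"high": labels.astype(int)}), time, event)
    hr = fit.hr("high")
    ci = (
        float(fit.summary.loc["high", "ci_lower"]),
        float(fit.summary.loc["high", "ci_upper"]),
    )

    relapse = rfs_e.astype(int)  # relapse-ever labels
    roc = roc_analysis(scores.to_numpy(), relapse)
    pred_high = scores.to_numpy() >= roc.chosen_threshold
    accuracy = float(np.mean(pred_high == relapse.astype(bool)))

    return PerformanceReport(
        signature=sig.name or "signature",
        endpoint=endpoint.upper(),
        hr=hr,
        hr_ci=ci,
        hr_p=float(fit.summary.loc["high", "p"]),
        logrank_chi2=lr.chi2,
        logrank_p=lr.p,
        auc=roc.auc,
        sensitivity=roc.chosen_sensitivity,
        specificity=roc.chosen_specificity,
        accuracy=accuracy,
        score_cutoff=cutoff,
        n_high=int(labels.sum()),
        n_low=int((~labels).sum()),
        km_high=km_estimate(time[labels], event[labels]),
        km_low=km_estimate(time[~labels], event[~labels]),
        roc=roc,
    )


def multivariate_report(sig_labels, covariates: pd.DataFrame, time, event) -> pd.DataFrame:
    """Joint Cox model of signature label + clinicopathologic covariates.

    Missing covariate values drop samples (complete-case).  Returns a
    table with one row per variable: HR, 95% CI, p; degenerate designs are
    reported through the fit's flags (logged)."""
    labels = np.asarray(sig_labels).astype(int)
    design = pd.DataFrame(covariates).copy() if covariates is not None else pd.DataFrame(index=range(len(labels)))
    design.insert(0, "signature_high", labels)
    design = design.reset_index(drop=True)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    complete = design.notna().all(axis=1).to_numpy()
    if not complete.all():
        logger.warning("multivariate_report: dropping %d incomplete samples", (~complete).sum())
    fit = cox_fit(design.loc[complete], time[complete], event[complete])
    for flag in fit.flags:
        logger.warning("multivariate_report: %s", flag)
    table = fit.summary.copy()
    table["hr_95ci"] = [
        f"{r.hr:.2f} ({r.ci_lower:.2f}-{r.ci_upper:.2f})" for r in table.itertuples()
    ]
    table.attrs["converged"] = fit.converged
    table.attrs["flags"] = fit.flags
    return table


@dataclass
class StratifiedKMReport:
    groups: dict  # (score_label, pt) -> KMCurve
    group_sizes: dict
    contrasts: dict  # score_label -> logrank p of pT4 vs pT3 within stratum
    omitted: list = field(default_factory=list)


def combined_pt_stratification(sig_labels, pt, time, event) -> StratifiedKMReport:
    """Four-group KM (score high/low × pT3/pT4) with pairwise log-rank of
    pT within each score stratum; empty contrasts are omitted with a
    warning."""
    labels = np.asarray(sig_labels).astype(bool)
    pt = np.asarray(pt, dtype=float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)

    groups, sizes, contrasts, omitted = {}, {}, {}, []
    for score_label, mask in (("high", labels), ("low", ~labels)):
        for level in (3, 4):
            sel = mask & (pt == level)
            key = (score_label, f"pT{level}")
            sizes[key] = int(sel.sum())
            if sel.any():
                groups[key] = km_estimate(time[sel], event[sel])
        m3 = mask & (pt == 3)
        m4 = mask & (pt == 4)
        if m3.any() and m4.any():
            lr = logrank_test([(time[m4], event[m4]), (time[m3], event[m3])])
            contrasts[score_label] = lr.p
        else:
            omitted.append(score_label)
            logger.warning("pT contrast omitted in %s-score stratum (empty level)", score_label)
    return StratifiedKMReport(groups=groups, group_sizes=sizes, contrasts=contrasts, omitted=omitted)


@dataclass
class ComparisonReport:
    report_a: PerformanceReport
    report_b: PerformanceReport
    concordance: pd.DataFrame  # 2×2: rows sig A high/low, cols sig B high/low
    high_risk_difference: int  # n_high(B) - n_high(A)

    @property
    def concordant_fraction(self) -> float:
        total = self.concordance.to_numpy().sum()
        return float(np.trace(self.concordance.to_numpy()) / total)


def compare_signatures(
    sig_a: Signature, sig_b: Signature, cohort: Cohort, endpoint: str = "RFS"
) -> ComparisonReport:
    """Head-to-head comparison with per-patient high/low concordance."""
    rep_a = evaluate_signature(sig_a, cohort, endpoint)
    rep_b = evaluate_signature(sig_b, cohort, endpoint)
    rfs_t, rfs_e = cohort.survival("RFS")
    scores_a = recurrence_scores(sig_a, cohort).to_numpy()
    scores_b = recurrence_scores(sig_b, cohort).to_numpy()
    high_a = scores_a > sig_a.score_cutoff[cohort.name]
    high_b = scores_b > sig_b.score_cutoff[cohort.name]
    table = pd.DataFrame(
        [
            [int((high_a & high_b).sum()), int((high_a & ~high_b).sum())],
            [int((~high_a & high_b).sum()), int((~high_a & ~high_b).sum())],
        ],
        index=["a_high", "a_low"],
        columns=["b_high", "b_low"],
    )
    return ComparisonReport(
        report_a=rep_a,
        report_b=rep_b,
        concordance=table,
        high_risk_difference=int(high_b.sum() - high_a.sum()),
    )


def save_roc_plot(roc, path) -> None:
    """ROC curve with the chosen operating point highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(1.0 - roc.specificity, roc.sensitivity, color="tab:blue")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.plot(
        1.0 - roc.chosen_specificity, roc.chosen_sensitivity, "o", color="tab:red",
        label=f"threshold {roc.chosen_threshold:.3g}",
    )
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {roc.auc:.3f}")
    ax.legend(frameon=False, loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_km_plot(report: PerformanceReport, path) -> None:
    """Two-group KM step plot for a performance report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, label, color in (
        (report.km_low, f"low (n={report.n_low})", "tab:blue"),
        (report.km_high, f"high (n={report.n_high})", "tab:red"),
    ):
        if curve is None or curve.event_times.size == 0:
            continue
        x = np.r_[0, np.repeat(curve.event_times, 2)]
        y = np.r_[1, 1, np.repeat(curve.survival, 2)[:-1]]
        ax.plot(x, y, label=label, color=color)
    ax.set_xlabel("months")
    ax.set_ylabel(f"{report.endpoint} probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    ax.set_title(f"{report.signature}: HR={report.hr:.2f}, p={report.logrank_p:.2e}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
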