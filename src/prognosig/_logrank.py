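"""Vectorized pooled-risk-set log-rank machinery.

Everything cut-off related in this package — the maximally selected rank
statistic for single genes, high/low classification of integer recurrence
scores, and the batched evaluation of thousands of gene combinations inside
the beam search — reduces to the same computation: given a fixed sample of
(time, event) pairs and many candidate binary group assignments, compute the
two-group log-rank statistic for every assignment.  This module precomputes
the risk-set structure once per survival sample (`SurvivalIndex`) and then
evaluates whole matrices of group indicators in a handful of numpy
operations.

Conventions
-----------
Group 1 is the "high" group.  The signed standardized statistic is
z = (O1 - E1) / sqrt(V); z > 0 means group 1 experienced more events than
expected under the null, i.e. high values are unfavorable.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


class NoAdmissibleSplitError(ValueError):
    """No candidate cutpoint satisfies the minimum-proportion constraint."""


class SurvivalIndex:
    """Precomputed risk-set structure for a fixed (time, event) sample.

    Parameters
    ----------
    time : array-like of nonnegative floats, months.
    event : array-like of {0, 1}; 1 = event observed.
    """

    def __init__(self, time, event):
        time = np.asarray(time, dtype=np.float64)
        event = np.asarray(event)
        if time.ndim != 1 or time.size == 0:
            raise ValueError("time must be a nonempty 1-d array")
        if np.any(~np.isfinite(time)) or np.any(time < 0):
            raise ValueError("survival times must be finite and nonnegative")
        uniq = np.unique(event)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("event indicators must be 0 or 1")
        if event.shape != time.shape:
            raise ValueError("time and event must have the same shape")

        self.time = time
        self.event = event.astype(np.float64)
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        t_sorted = time[self.order]
        self.d_sorted = self.event[self.order]
        # segment starts of distinct times in the time-sorted sample
        self.starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
        deaths = np.add.reduceat(self.d_sorted, self.starts)
        self.event_mask = deaths > 0
        # at-risk counts: sorted ascending, so risk set at a distinct time is
        # every sample at or after its first index
        self.n_risk = (self.n - self.starts)[self.event_mask].astype(np.float64)
        self.n_events = deaths[self.event_mask]
        self.event_times = t_sorted[self.starts][self.event_mask]
        self.total_events = float(self.d_sorted.sum())


def two_group_stats(groups, idx: SurvivalIndex):
    """Log-rank O-E, variance and signed z for each row of `groups`.

    Parameters
    ----------
    groups : bool/int array (m, n) or (n,); membership of group 1 ("high"),
        in the original (unsorted) sample order of `idx`.

    Returns
    -------
    o_minus_e, var, z : float arrays of shape (m,)
    """
    G = np.atleast_2d(np.asarray(groups)).astype(np.float64)
    if G.shape[1] != idx.n:
        raise ValueError("group matrix width does not match sample size")
    m = G.shape[0]
    if idx.event_times.size == 0:
        zeros = np.zeros(m)
        return zeros, zeros.copy(), zeros.copy()

    Gt = G[:, idx.order]
    seg = np.add.reduceat(Gt, idx.starts, axis=1)
    # suffix sums over distinct-time segments = group-1 at-risk counts
    n1 = np.cumsum(seg[:, ::-1], axis=1)[:, ::-1][:, idx.event_mask]
    d1 = np.add.reduceat(Gt * idx.d_sorted, idx.starts, axis=1)[:, idx.event_mask]

    n_risk = idx.n_risk
    d = idx.n_events
    frac = n1 / n_risk
    o_minus_e = (d1 - d * frac).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac * (1.0 - frac) * (n_risk - d) / (n_risk - 1.0)
    v[:, n_risk <= 1.0] = 0.0
    var = v.sum(axis=1)
    z = np.zeros(m)
    ok = var > 0
    z[ok] = o_minus_e[ok] / np.sqrt(var[ok])
    return o_minus_e, var, z


def _admissible(n_high, n_total, minprop):
    lo = minprop * n_total
    n_low = n_total - n_high
    return (n_high >= lo) & (n_low >= lo)


def scan_cutpoints(values, idx: SurvivalIndex, minprop=0.1):
    """Maximally selected log-rank scan over midpoints of consecutive values.

    Returns a dict with the selected cutpoint (smallest on exact statistic
    ties), the signed z there, chi2, p, and group sizes.  Raises
    `NoAdmissibleSplitError` when no split keeps at least ``minprop`` of the
    samples on both sides (including the constant-values case).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (idx.n,):
        raise ValueError("values length does not match survival sample")
    if np.any(~np.isfinite(values)):
        raise ValueError("expression values must be finite")
    uniq = np.unique(values)
    if uniq.size < 2:
        raise NoAdmissibleSplitError("constant values admit no split")
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    G = values[None, :] > cuts[:, None]
    n_high = G.sum(axis=1)
    adm = _admissible(n_high, idx.n, minprop)
    if not adm.any():
        raise NoAdmissibleSplitError(
            f"no split satisfies minprop={minprop} on both sides"
        )
    cuts = cuts[adm]
    G = G[adm]
    n_high = n_high[adm]
    _, _, z = two_group_stats(G, idx)
    best = int(np.argmax(np.abs(z)))  # first occurrence = smallest cutpoint
    chi2 = float(z[best] ** 2)
    return {
        "cutpoint": float(cuts[best]),
        "z": float(z[best]),
        "chi2": chi2,
        "p": float(stats.chi2.sf(chi2, 1)) if idx.total_events > 0 else 1.0,
        "n_high": int(n_high[best]),
        "n_low": int(idx.n - n_high[best]),
    }


def scan_score_cuts(scores, idx: SurvivalIndex, minprop=0.1):
    """Best high/low cut for each row of an integer score matrix.

    Scans the shared grid of integer cut levels c (group 1 = score > c,
    reported cutpoint c + 0.5).  Rows without any admissible cut are flagged
    uninformative: p = 1, cutpoint = nan.

    Returns
    -------
    dict of arrays: cutpoint, chi2, p, z, informative (bool), all shape (m,).
    """
    S = np.atleast_2d(np.asarray(scores))
    m = S.shape[0]
    if S.shape[1] != idx.n:
        raise ValueError("score matrix width does not match sample size")
    lo_val = int(S.min())
    hi_val = int(S.max())
    levels = np.arange(lo_val, hi_val)  # cut after each level except the top
    chi2 = np.full((m, levels.size), -np.inf)
    zmat = np.zeros((m, levels.size))

    # batched fast path: columns pre-sorted by time, float32 passes
    St = np.ascontiguousarray(S[:, idx.order])
    d32 = idx.d_sorted.astype(np.float32)
    n_risk = idx.n_risk.astype(np.float32)
    d_ev = idx.n_events.astype(np.float32)
    has_events = idx.event_times.size > 0
    for j, c in enumerate(levels):
        G = St > c
        n_high = G.sum(axis=1)
        adm = _admissible(n_high, idx.n, minprop)
        if not adm.any():
            continue
        if not has_events:
            chi2[adm, j] = 0.0
            continue
        Ga = G[adm].astype(np.float32)
        seg = np.add.reduceat(Ga, idx.starts, axis=1)
        n1 = np.cumsum(seg[:, ::-1], axis=1)[:, ::-1][:, idx.event_mask]
        d1 = np.add.reduceat(Ga * d32, idx.starts, axis=1)[:, idx.event_mask]
        frac = n1 / n_risk
        o_minus_e = (d1 - d_ev * frac).sum(axis=1, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = d_ev * frac * (1.0 - frac) * (n_risk - d_ev) / (n_risk - 1.0)
        v[:, n_risk <= 1.0] = 0.0
        var = v.sum(axis=1, dtype=np.float64)
        z = np.zeros(var.size)
        ok = var > 0
        z[ok] = o_minus_e[ok] / np.sqrt(var[ok])
        chi2[adm, j] = z**2
        zmat[adm, j] = z
    informative = np.isfinite(chi2).any(axis=1)
    out_cut = np.full(m, np.nan)
    out_chi2 = np.zeros(m)
    out_p = np.ones(m)
    out_z = np.zeros(m)
    if informative.any() and levels.size:
        best_j = np.argmax(chi2[informative], axis=1)  # first max = smallest cut
        rows = np.flatnonzero(informative)
        out_cut[rows] = levels[best_j] + 0.5
        out_chi2[rows] = chi2[rows, best_j]
        out_z[rows] = zmat[rows, best_j]
        if idx.total_events > 0:
            out_p[rows] = stats.chi2.sf(out_chi2[rows], 1)
    return {
        "cutpoint": out_cut,
        "chi2": out_chi2,
        "p": out_p,
        "z": out_z,
        "informative": informative,
    }
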