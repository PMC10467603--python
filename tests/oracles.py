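"""Independent brute-force oracles used to check the package's survival
primitives.  Everything here is written from the textbook definitions —
explicit loops, exact rational arithmetic where possible — and never calls
the implementation paths it checks."""

from fractions import Fraction
from itertools import combinations

import numpy as np


def product_limit_exact(times, events):
    """Kaplan–Meier by direct product over distinct event times, in exact
    rational arithmetic.  Returns (event_times, survival Fractions, at_risk)."""
    times = list(times)
    events = list(events)
    n = len(times)
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    surv, at_risk = [], []
    s = Fraction(1)
    for tau in distinct:
        n_risk = sum(1 for t in times if t >= tau)
        d = sum(1 for t, e in zip(times, events) if t == tau and e == 1)
        s *= Fraction(n_risk - d, n_risk)
        surv.append(s)
        at_risk.append(n_risk)
    return distinct, surv, at_risk


def logrank_two_group(time, event, high):
    """O-E, hypergeometric variance and chi-square for a two-group log-rank,
    via an explicit loop over distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    high = np.asarray(high, bool)
    o_minus_e = 0.0
    var = 0.0
    for tau in sorted(set(time[event == 1])):
        at_risk = time >= tau
        n = at_risk.sum()
        n1 = (at_risk & high).sum()
        d = ((time == tau) & (event == 1)).sum()
        d1 = ((time == tau) & (event == 1) & high).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return o_minus_e, var, chi2


def exhaustive_cutpoint(values, time, event, minprop=0.1):
    """Full scan over midpoints of consecutive unique values; returns
    (cutpoint, |z|) of the maximal standardized log-rank statistic, with the
    smallest cutpoint on ties."""
    values = np.asarray(values, float)
    n = values.size
    uniq = np.sort(np.unique(values))
    best = None
    for c in (uniq[:-1] + uniq[1:]) / 2:
        high = values > c
        n_high = high.sum()
        if n_high < minprop * n or (n - n_high) < minprop * n:
            continue
        ome, var, _ = logrank_two_group(time, event, high)
        absz = abs(ome) / np.sqrt(var) if var > 0 else 0.0
        if best is None or absz > best[1] + 1e-12:
            best = (c, absz)
    return best


def auc_concordance(scores, labels):
    """AUC as the pairwise concordance probability with 1/2 for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def enumerate_best_per_k(gene_names, evaluate, max_k):
    """Best (lowest-p) combination at every size k by full enumeration.

    ``evaluate`` maps a tuple of genes to an object with a ``p`` attribute.
    """
    best = {}
    for k in range(2, max_k + 1):
        for combo in combinations(gene_names, k):
            res = evaluate(combo)
            cur = best.get(k)
            if cur is None or res.p < cur.p:
                best[k] = res
    return best


def random_survival(rng, n, censor_frac=0.4, tie_prob=0.0):
    """Small random right-censored sample, optionally with tied times."""
    time = rng.exponential(10.0, size=n)
    if tie_prob > 0:
        time = np.ceil(time)  # force ties
    event = (rng.random(n) > censor_frac).astype(int)
    return time, event
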