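"""Beam-search refinement of gene signatures.

Starting from all 2-gene combinations of a candidate pool, the search keeps
the ``beam_width`` most significant combinations at each size k (log-rank p
of the combination's high/low recurrence-score classifier), extends each
survivor by every remaining pool gene, and repeats until ``max_k``.  The
per-k best combination is recorded in a trace; the selected signature size
is the trace's significance peak.

Combinations are subsets: duplicates arising from different extension paths
are merged by set identity.  All tie-breaks are fully specified (p, then
lexicographic gene order), so a fixed input yields a byte-identical trace.
Every combination re-optimizes its integer score cut-off, which is cheap
because scores range over 0..k.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from ._logrank import SurvivalIndex, scan_score_cuts
from .scoring import Signature, SignatureGene, compute_gene_cutoffs, _points_matrix

__all__ = [
    "Combination",
    "RefinementTrace",
    "evaluate_combination",
    "beam_step",
    "beam_refine",
    "select_signature_size",
    "BeamSignatureSelector",
]


@dataclass(frozen=True)
class Combination:
    genes: frozenset
    p: float
    chi2: float
    score_cutoff: float
    informative: bool = True


@dataclass
class RefinementTrace:
    """Per-size best combinations from a beam run."""

    entries: list = field(default_factory=list)  # list of Combination, ascending k

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [len(c.genes) for c in self.entries],
                "p": [c.p for c in self.entries],
                "neg_log10_p": [-np.log10(max(c.p, 5e-324)) for c in self.entries],
                "chi2": [c.chi2 for c in self.entries],
                "score_cutoff": [c.score_cutoff for c in self.entries],
                "genes": [",".join(sorted(c.genes)) for c in self.entries],
            }
        )


def _evaluate_rows(rows: np.ndarray, points: np.ndarray, idx: SurvivalIndex, minprop: float):
    """Evaluate combination rows (m, P bool) against a point matrix (P, n)."""
    scores = rows.astype(np.float64) @ points.astype(np.float64)
    return scan_score_cuts(scores, idx, minprop=minprop)


def _rank_rows(rows: np.ndarray, res: dict):
    """Deterministic ordering: p ascending, then lexicographic gene indices."""
    keys = []
    for i in range(rows.shape[0]):
        keys.append((res["p"][i], tuple(np.flatnonzero(rows[i])), i))
    keys.sort(key=lambda t: t[:2])
    return [t[2] for t in keys]


def _dedup_rows(rows: np.ndarray) -> np.ndarray:
    packed = np.packbits(rows, axis=1)
    _, first = np.unique(packed, axis=0, return_index=True)
    return rows[np.sort(first)]


class _BeamState:
    def __init__(self, rows, res, order, k):
        self.rows = rows  # (m, P) bool, sorted by rank
        self.res = res
        self.order = order
        self.k = k

    def best(self, gene_names) -> Combination:
        i = self.order[0]
        return Combination(
            genes=frozenset(gene_names[j] for j in np.flatnonzero(self.rows[i])),
            p=float(self.res["p"][i]),
            chi2=float(self.res["chi2"][i]),
            score_cutoff=float(self.res["cutpoint"][i])
            if np.isfinite(self.res["cutpoint"][i])
            else float("nan"),
            informative=bool(self.res["informative"][i]),
        )


def _make_state(rows, points, idx, minprop, beam_width, k) -> _BeamState:
    res = _evaluate_rows(rows, points, idx, minprop)
    order = _rank_rows(rows, res)
    if beam_width is not None and len(order) > beam_width:
        order = order[:beam_width]
    keep = np.array(order)
    rows = rows[keep]
    res = {key: val[keep] for key, val in res.items()}
    return _BeamState(rows, res, list(range(rows.shape[0])), k)


def beam_step(state: _BeamState, points, idx, minprop, beam_width) -> _BeamState:
    """Extend every beam member by every pool gene not already in it."""
    rows = state.rows
    if rows.shape[0] == 0:
        raise ValueError("empty beam")
    m, P = rows.shape
    if state.k >= P:
        raise ValueError("combination size already equals pool size")
    ext = np.repeat(rows, P, axis=0)
    add = np.tile(np.eye(P, dtype=bool), (m, 1))
    valid = ~(ext & add).any(axis=1)
    ext = ext[valid] | add[valid]
    ext = _dedup_rows(ext)
    return _make_state(ext, points, idx, minprop, beam_width, state.k + 1)


def beam_refine(
    points: np.ndarray,
    time,
    event,
    gene_names,
    beam_width: int | None = 2000,
    max_k: int | None = None,
    minprop: float = 0.1,
    prune_only_first: bool = False,
) -> RefinementTrace:
    """Run the beam search over a per-gene 0/1 point matrix.

    Parameters
    ----------
    points : (P, n) 0/1 matrix of per-gene points (gene cut-offs already
        applied, direction-aware).
    beam_width : combinations retained per size; None means unlimited
        (exhaustive subset enumeration).
    prune_only_first : if True, prune to ``beam_width`` only at k=2 and keep
        every extension afterwards (the single-prune reading of the search).
    """
    points = np.asarray(points)
    P = points.shape[0]
    gene_names = list(gene_names)
    if P != len(gene_names):
        raise ValueError("points / gene_names mismatch")
    if P < 2:
        raise ValueError("candidate pool must hold at least 2 genes")
    max_k = P if max_k is None else min(max_k, P)
    idx = SurvivalIndex(time, event)

    pairs = np.zeros((P * (P - 1) // 2, P), dtype=bool)
    for r, (i, j) in enumerate(itertools.combinations(range(P), 2)):
        pairs[r, i] = pairs[r, j] = True
    state = _make_state(pairs, points, idx, minprop, beam_width, 2)
    trace = RefinementTrace([state.best(gene_names)])
    width = None if prune_only_first else beam_width
    while state.k < max_k:
        state = beam_step(state, points, idx, minprop, width)
        trace.entries.append(state.best(gene_names))
    return trace


def select_signature_size(trace: RefinementTrace):
    """(k*, best Combination): significance peak of the trace, smallest k on
    ties."""
    if not trace.entries:
        raise ValueError("empty trace")
    best = min(trace.entries, key=lambda c: (c.p, len(c.genes)))
    return len(best.genes), best


def evaluate_combination(genes, cohort, directions: dict, minprop: float = 0.1) -> Combination:
    """Score one gene combination on a cohort (cut-offs recomputed).

    ``genes`` must be duplicate-free; a combination whose recurrence scores
    admit no high/low split is flagged uninformative with p = 1.
    """
    genes = list(genes)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate genes in combination")
    sig = Signature(genes=[SignatureGene(g, directions[g]) for g in genes])
    cutoffs = compute_gene_cutoffs(sig, cohort, minprop=minprop)
    points = _points_matrix(sig, cohort.expr, cutoffs)
    time, event = cohort.survival("RFS")
    idx = SurvivalIndex(time, event)
    res = scan_score_cuts(points.sum(axis=0)[None, :], idx, minprop=minprop)
    return Combination(
        genes=frozenset(genes),
        p=float(res["p"][0]),
        chi2=float(res["chi2"][0]),
        score_cutoff=float(res["cutpoint"][0]) if res["informative"][0] else float("nan"),
        informative=bool(res["informative"][0]),
    )


class BeamSignatureSelector(BaseEstimator):
    """Beam-search signature selection as a scikit-learn style selector.

    Parameters
    ----------
    directions : dict gene -> 'favorable'/'unfavorable' for every candidate
        column of X used in the search (columns without a direction are
        ignored).
    beam_width : beam size B (2000 mirrors the published search); None for
        exhaustive enumeration.
    max_k : largest combination size to explore (default: pool size).

    Attributes
    ----------
    trace_ : RefinementTrace; best_k_ : selected size; best_genes_ : list;
    signature_ : Signature with frozen per-gene and score cut-offs.
    """

    def __init__(
        self,
        directions: dict | None = None,
        beam_width: int | None = 2000,
        max_k: int | None = None,
        minprop: float = 0.1,
        prune_only_first: bool = False,
    ):
        self.directions = directions
        self.beam_width = beam_width
        self.max_k = max_k
        self.minprop = minprop
        self.prune_only_first = prune_only_first

    def fit(self, X: pd.DataFrame, y):
        from .scoring import RecurrenceScoreClassifier
        from .survstats import optimal_cutpoint

        if not self.directions:
            raise ValueError("directions must map candidate genes to favorable/unfavorable")
        time, event = RecurrenceScoreClassifier._surv_arrays(y)
        X = pd.DataFrame(X)
        pool = [g for g in X.columns if g in self.directions]
        if len(pool) < 2:
            raise ValueError("fewer than 2 candidate genes present in X")

        self.cutoffs_ = {}
        rows = []
        for g in pool:
            x = X[g].to_numpy(dtype=float)
            cut = optimal_cutpoint(x, time, event, minprop=self.minprop).cutpoint
            self.cutoffs_[g] = cut
            rows.append(x > cut if self.directions[g] == "unfavorable" else x < cut)
        points = np.asarray(rows, dtype=np.uint8)

        self.trace_ = beam_refine(
            points,
            time,
            event,
            pool,
            beam_width=self.beam_width,
            max_k=self.max_k,
            minprop=self.minprop,
            prune_only_first=self.prune_only_first,
        )
        self.best_k_, best = select_signature_size(self.trace_)
        self.best_genes_ = sorted(best.genes)
        self.signature_ = Signature(
            genes=[SignatureGene(g, self.directions[g]) for g in self.best_genes_],
            cutoffs={"train": {g: self.cutoffs_[g] for g in self.best_genes_}},
            score_cutoff={"train": best.score_cutoff},
            name=f"beam-{self.best_k_}gene",
        )
        self._pool = pool
        return self

    def get_support(self, X_columns=None):
        if not hasattr(self, "best_genes_"):
            raise NotFittedError("fit the selector first")
        cols = list(X_columns) if X_columns is not None else self._pool
        chosen = set(self.best_genes_)
        return np.array([c in chosen for c in cols])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "best_genes_"):
            raise NotFittedError("fit the selector first")
        return pd.DataFrame(X)[self.best_genes_]
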