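"""Recurrence-score system: per-gene 0/1 points against direction-specific
expression cut-offs, signature-level integer scores, high/low
classification, and the Oncotype DX colon RS_U comparator.

An *unfavorable* gene (high expression → poor survival) contributes a point
when expression exceeds its cut-off; a *favorable* gene contributes a point
when expression falls below its cut-off.  A sample exactly at a cut-off
scores 0 under either direction — a conservative tie rule that is
measure-zero for continuous data.  The signature score is the sum over
genes, so it ranges over 0..|genes|, and high scores mean high expression
of unfavorable genes and low expression of favorable ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .cohorts import Cohort
from .survstats import CutpointResult, optimal_cutpoint

DIRECTIONS = ("favorable", "unfavorable")

#: Aliases for symbols the assay literature prints under legacy names.
GENE_ALIASES = {"KI67": "MKI67"}


def resolve_gene(gene: str, available) -> str:
    """Find `gene` in an index, falling back to its alias; KeyError if absent."""
    if gene in available:
        return gene
    alias = GENE_ALIASES.get(gene)
    if alias is not None and alias in available:
        return alias
    raise KeyError(f"gene {gene!r} not present in expression matrix")


@dataclass(frozen=True)
class SignatureGene:
    gene: str
    direction: str

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")


@dataclass
class Signature:
    """An ordered set of (gene, direction) pairs with optional frozen
    cut-offs (cohort -> gene -> value) and high/low score cut-offs."""

    genes: list
    cutoffs: dict = field(default_factory=dict)
    score_cutoff: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate genes in signature")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_names(self) -> list:
        return [g.gene for g in self.genes]

    def direction_of(self, gene: str) -> str:
        for g in self.genes:
            if g.gene == gene:
                return g.direction
        raise KeyError(gene)

    def to_json(self, path=None):
        payload = {
            "name": self.name,
            "genes": [{"gene": g.gene, "direction": g.direction} for g in self.genes],
            "cutoffs": self.cutoffs,
            "score_cutoff": self.score_cutoff,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, source) -> "Signature":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            genes=[SignatureGene(g["gene"], g["direction"]) for g in payload["genes"]],
            cutoffs=payload.get("cutoffs", {}),
            score_cutoff=payload.get("score_cutoff", {}),
            name=payload.get("name", ""),
        )

    @classmethod
    def packaged(cls, key: str) -> "Signature":
        """Load a definition shipped with the package: '15gene' or 'oncotype7'."""
        fname = {"15gene": "signature_15gene.json", "oncotype7": "signature_oncotype7.json"}
        if key not in fname:
            raise KeyError(f"no packaged signature {key!r}")
        text = resources.files("prognosig.data").joinpath(fname[key]).read_text()
        return cls.from_json(text)


def gene_point(x: float, cutoff: float, direction: str) -> int:
    """0/1 point for one gene: strict comparison, equality scores 0."""
    if direction == "unfavorable":
        return int(x > cutoff)
    if direction == "favorable":
        return int(x < cutoff)
    raise ValueError(f"unknown direction {direction!r}")


def _points_matrix(sig: Signature, expr: pd.DataFrame, cutoffs: dict) -> np.ndarray:
    """(len(sig), n_samples) uint8 matrix of per-gene points."""
    rows = []
    for g in sig.genes:
        key = resolve_gene(g.gene, expr.index)
        x = expr.loc[key].to_numpy(dtype=float)
        c = cutoffs[g.gene]
        rows.append(x > c if g.direction == "unfavorable" else x < c)
    return np.asarray(rows, dtype=np.uint8)


def compute_gene_cutoffs(sig: Signature, cohort: Cohort, minprop: float = 0.1) -> dict:
    """Per-gene optimal cut-offs (maximally selected log-rank) on RFS."""
    time, event = cohort.survival("RFS")
    cutoffs = {}
    for g in sig.genes:
        key = resolve_gene(g.gene, cohort.expr.index)
        res: CutpointResult = optimal_cutpoint(
            cohort.expr.loc[key].to_numpy(dtype=float), time, event, minprop=minprop
        )
        cutoffs[g.gene] = res.cutpoint
    return cutoffs


def recurrence_scores(
    sig: Signature, cohort: Cohort, minprop: float = 0.1, frozen: bool = False
) -> pd.Series:
    """Integer recurrence score per sample (sum of gene points).

    Cut-offs come from the signature's stored map for this cohort when
    ``frozen`` (applying a trained signature to new samples); otherwise they
    are recomputed per cohort and cached on the signature.
    """
    if frozen:
        if cohort.name not in sig.cutoffs:
            raise ValueError(f"no frozen cutoffs for cohort {cohort.name!r}")
        cutoffs = sig.cutoffs[cohort.name]
    else:
        cutoffs = sig.cutoffs.get(cohort.name)
        if cutoffs is None or set(cutoffs) != set(sig.gene_names):
            cutoffs = compute_gene_cutoffs(sig, cohort, minprop=minprop)
            sig.cutoffs[cohort.name] = cutoffs
    points = _points_matrix(sig, cohort.expr, cutoffs)
    return pd.Series(points.sum(axis=0).astype(int), index=cohort.samples, name="score")


def classify_high_low(scores, time, event, minprop: float = 0.1):
    """Dichotomize integer recurrence scores at their optimal cut-off.

    Returns (labels, cutoff): labels is a boolean array (True = high) and
    cutoff the selected midpoint.  Constant scores are an error.
    """
    values = np.asarray(scores, dtype=float)
    if np.unique(values).size < 2:
        raise ValueError("constant scores cannot be classified")
    res = optimal_cutpoint(values, time, event, minprop=minprop)
    return values > res.cutpoint, res.cutpoint


ONCOTYPE_UNFAVORABLE = ("BGN", "FAP", "INHBA", "GADD45B")
ONCOTYPE_FAVORABLE = ("MYBL2", "KI67", "MYC")


def oncotype_rs_u(expr: pd.DataFrame) -> pd.Series:
    """Published linear Oncotype DX colon recurrence score:
    RS_U = 0.15·(BGN+FAP+INHBA)/3 − 0.3·(MYBL2+KI67+MYC)/3 + 0.15·GADD45B.
    """
    need = ("BGN", "FAP", "INHBA", "MYBL2", "KI67", "MYC", "GADD45B")
    vals = {g: expr.loc[resolve_gene(g, expr.index)].astype(float) for g in need}
    rs = (
        0.15 * (vals["BGN"] + vals["FAP"] + vals["INHBA"]) / 3.0
        - 0.3 * (vals["MYBL2"] + vals["KI67"] + vals["MYC"]) / 3.0
        + 0.15 * vals["GADD45B"]
    )
    rs.name = "RS_U"
    return rs


def score_based_oncotype(cohort: Cohort, minprop: float = 0.1) -> pd.Series:
    """Apply this package's 0/1 cut-off scoring to the seven Oncotype genes,
    with directions taken from the signs of the RS_U formula."""
    sig = Signature.packaged("oncotype7")
    return recurrence_scores(sig, cohort, minprop=minprop)


class RecurrenceScoreClassifier(BaseEstimator):
    """Signature-based high/low relapse-risk classifier.

    Fitting learns per-gene expression cut-offs and the score cut-off by
    maximally selected log-rank statistics against the survival outcome;
    `decision_function` returns integer recurrence scores and `predict`
    the 0/1 high-risk call.

    Parameters
    ----------
    signature : Signature, or a packaged key ('15gene', 'oncotype7').
    minprop : minimum fraction of samples on each side of any cut-off.

    Attributes
    ----------
    cutoffs_ : dict gene -> expression cut-off.
    score_cutoff_ : float, high/low threshold on the integer score.
    """

    def __init__(self, signature="15gene", minprop: float = 0.1):
        self.signature = signature
        self.minprop = minprop

    def _sig(self) -> Signature:
        if isinstance(self.signature, Signature):
            return self.signature
        return Signature.packaged(self.signature)

    @staticmethod
    def _surv_arrays(y):
        if isinstance(y, tuple):
            return np.asarray(y[0], float), np.asarray(y[1], int)
        y = np.asarray(y)
        if y.dtype.names:  # scikit-survival style structured array
            names = y.dtype.names
            ev = y[names[0]].astype(int)
            t = y[names[1]].astype(float)
            return t, ev
        raise ValueError("y must be (time, event) or a structured (event, time) array")

    def fit(self, X: pd.DataFrame, y):
        """X: samples × genes DataFrame; y: survival outcome."""
        time, event = self._surv_arrays(y)
        sig = self._sig()
        expr = pd.DataFrame(X).T  # genes × samples
        self.cutoffs_ = {}
        for g in sig.genes:
            key = resolve_gene(g.gene, expr.index)
            res = optimal_cutpoint(
                expr.loc[key].to_numpy(dtype=float), time, event, minprop=self.minprop
            )
            self.cutoffs_[g.gene] = res.cutpoint
        self.signature_ = Signature(genes=list(sig.genes), name=sig.name or "fitted")
        points = _points_matrix(self.signature_, expr, self.cutoffs_)
        scores = points.sum(axis=0).astype(int)
        _, self.score_cutoff_ = classify_high_low(scores, time, event, minprop=self.minprop)
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "cutoffs_"):
            raise NotFittedError("fit the classifier first")
        expr = pd.DataFrame(X).T
        points = _points_matrix(self.signature_, expr, self.cutoffs_)
        return points.sum(axis=0).astype(int)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.decision_function(X) > self.score_cutoff_).astype(int)
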