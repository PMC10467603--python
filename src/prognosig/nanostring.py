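"""Two-step normalization and QC for NanoString-style raw count tables.

Digital counting panels carry three probe classes: endogenous test genes,
housekeeping genes, and a dilution series of synthetic positive controls.
Lane/hybridization efficiency differences are multiplicative, so both
normalization steps equalize per-sample *geometric* means of a control
class: first the positive controls (technical lane effect), then the
housekeeping genes (RNA input), after which only endogenous genes remain.
A low-expression filter and a robust RLE/PCA outlier screen complete the
QC path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

PROBE_CLASSES = ("endogenous", "housekeeping", "positive_control")

#: Housekeeping panel for colorectal tumors; "TKL2" is kept as printed in the
#: assay design (likely TLK2) and can be overridden per table.
DEFAULT_HOUSEKEEPING = ("AKAP1", "DNAJC14", "SF3A1", "TBC1D10B", "TKL2", "TMUB2")

#: Pseudocount applied to control-class counts only, to keep geometric means
#: defined at zero without biasing endogenous values.
_CONTROL_PSEUDOCOUNT = 0.5


@dataclass
class RawCountTable:
    """Nonnegative count matrix (probes × samples) with probe classes."""

    counts: pd.DataFrame
    probe_class: pd.Series  # probe -> one of PROBE_CLASSES
    hk_genes: tuple = DEFAULT_HOUSEKEEPING

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        unknown = set(self.probe_class.unique()) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes: {sorted(unknown)}")
        missing = [p for p in self.counts.index if p not in self.probe_class.index]
        if missing:
            raise ValueError(f"probes without a class: {missing[:5]}")

    def of_class(self, cls: str) -> pd.DataFrame:
        probes = self.probe_class.index[self.probe_class == cls]
        return self.counts.loc[self.counts.index.intersection(probes)]


def read_raw_counts(path) -> RawCountTable:
    """CSV with columns: probe, class, then one column per sample."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected probe, class and sample columns")
    probe_col, class_col = df.columns[:2]
    probe_class = pd.Series(df[class_col].to_numpy(), index=df[probe_col])
    counts = df.set_index(probe_col).drop(columns=[class_col]).astype(float)
    return RawCountTable(counts=counts, probe_class=probe_class)


def write_raw_counts(table: RawCountTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "class", table.probe_class.loc[out.index].to_numpy())
    out.to_csv(path, index_label="probe")


def _geomean(block: pd.DataFrame) -> pd.Series:
    """Per-sample geometric mean of a control-class block.

    The pseudocount is applied only when the block contains zeros, so the
    clean (all-positive) case stays an exact geometric mean and control
    geomeans equalize exactly after normalization."""
    pseudo = _CONTROL_PSEUDOCOUNT if (block.to_numpy() == 0).any() else 0.0
    return np.exp(np.log(block + pseudo).mean(axis=0))


def _control_factors(table: RawCountTable, cls: str) -> pd.Series:
    block = table.of_class(cls)
    if block.empty:
        raise ValueError(f"no {cls} probes present")
    gm = _geomean(block)
    zero = block.sum(axis=0) == 0
    if zero.any():
        raise ValueError(f"all-zero {cls} counts in sample(s): {list(block.columns[zero])}")
    grand = float(np.exp(np.log(gm).mean()))
    return grand / gm


def positive_control_normalize(table: RawCountTable) -> RawCountTable:
    """Scale every sample so positive-control geometric means are equal."""
    factors = _control_factors(table, "positive_control")
    return RawCountTable(
        counts=table.counts * factors,
        probe_class=table.probe_class,
        hk_genes=table.hk_genes,
    )


def housekeeping_normalize(table: RawCountTable) -> pd.DataFrame:
    """Scale per sample by housekeeping geometric means; returns the
    endogenous-genes-only expression matrix."""
    factors = _control_factors(table, "housekeeping")
    endo = table.of_class("endogenous")
    if endo.empty:
        raise ValueError("no endogenous probes present")
    return endo * factors


def normalize_counts(table: RawCountTable) -> pd.DataFrame:
    """Full two-step normalization: positive controls then housekeeping."""
    return housekeeping_normalize(positive_control_normalize(table))


def low_expression_filter(expr: pd.DataFrame, threshold: float = 10.0):
    """Remove genes with mean counts per sample strictly below `threshold`.

    Returns (filtered matrix, list of removed genes).  The comparison is
    strict, so threshold 0 removes nothing; removing every gene is an error.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    means = expr.mean(axis=1)
    removed = list(expr.index[means < threshold])
    kept = expr.loc[means >= threshold]
    if kept.empty:
        raise ValueError("low-expression filter removed every gene")
    if removed:
        logger.info("low_expression_filter: removed %d genes", len(removed))
    return kept, removed


@dataclass
class QCReport:
    excluded_samples: list
    reasons: dict = field(default_factory=dict)  # sample -> reason string
    filtered_genes: list = field(default_factory=list)


def _robust_z(x: np.ndarray) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad
    if scale == 0:
        return np.zeros_like(x)
    return (x - med) / scale


def qc_flag_outliers(expr: pd.DataFrame, k_mad: float = 3.5) -> QCReport:
    """Flag dispersed samples by relative log expression (RLE) and PCA.

    A sample is flagged when its RLE median or RLE IQR deviates from the
    cohort by more than ``k_mad`` robust (MAD) deviations, or when its
    position in the first two principal components has robust z > ``k_mad``.
    Deterministic for fixed input.
    """
    if expr.shape[1] < 5:
        raise ValueError("QC requires at least 5 samples")
    log = np.log2(expr.to_numpy(dtype=float) + 1.0)
    if np.allclose(log, log[0, 0]):
        raise ValueError("degenerate (constant) matrix")
    rle = log - np.median(log, axis=1, keepdims=True)
    rle_med = np.median(rle, axis=0)
    rle_iqr = np.subtract(*np.percentile(rle, [75, 25], axis=0))

    flags: dict = {}
    for name, stat in (("RLE median", rle_med), ("RLE IQR", rle_iqr)):
        z = np.abs(_robust_z(stat))
        for i in np.flatnonzero(z > k_mad):
            flags.setdefault(expr.columns[i], []).append(
                f"{name} at {z[i]:.1f} robust deviations"
            )

    n_comp = min(2, expr.shape[1] - 1, expr.shape[0])
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(rle.T)
    for j in range(pcs.shape[1]):
        z = np.abs(_robust_z(pcs[:, j]))
        for i in np.flatnonzero(z > k_mad):
            flags.setdefault(expr.columns[i], []).append(
                f"PC{j + 1} at {z[i]:.1f} robust deviations"
            )

    excluded = [s for s in expr.columns if s in flags]
    return QCReport(
        excluded_samples=excluded,
        reasons={s: "; ".join(flags[s]) for s in excluded},
    )


class NanoStringNormalizer:
    """Estimator-style wrapper over the two-step normalization + QC path.

    `fit_transform(table)` runs positive-control and housekeeping
    normalization, the low-expression filter and (optionally) outlier
    exclusion, returning the cleaned endogenous matrix.  Fitted attributes:
    ``removed_genes_``, ``qc_report_``.
    """

    def __init__(self, threshold: float = 10.0, k_mad: float = 3.5, drop_outliers: bool = True):
        self.threshold = threshold
        self.k_mad = k_mad
        self.drop_outliers = drop_outliers

    def get_params(self, deep=True):
        return {
            "threshold": self.threshold,
            "k_mad": self.k_mad,
            "drop_outliers": self.drop_outliers,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, table: RawCountTable) -> pd.DataFrame:
        expr = normalize_counts(table)
        expr, self.removed_genes_ = low_expression_filter(expr, self.threshold)
        self.qc_report_ = qc_flag_outliers(expr, self.k_mad)
        self.qc_report_.filtered_genes = list(self.removed_genes_)
        if self.drop_outliers and self.qc_report_.excluded_samples:
            expr = expr.drop(columns=self.qc_report_.excluded_samples)
        return expr
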