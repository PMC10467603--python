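"""Cohort data model and I/O: expression + clinical tables, probe
collapsing, per-gene z-scoring and multi-cohort pooling.

An expression matrix is a pandas DataFrame with gene (or probe) symbols as
the index and sample ids as columns.  A `Cohort` joins one such matrix to a
clinical table indexed by sample id; samples without a complete relapse-free
survival record are dropped at construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = [
    "rfs_time_months",
    "rfs_event",
    "os_time_months",
    "os_event",
    "pt",
    "grade",
    "msi",
    "kras",
    "age",
    "sex",
]

_ENUM_VALUES = {
    "pt": {3, 4},
    "grade": {1, 2, 3},
    "msi": {"MSS", "MSI"},
    "kras": {"wt", "mut"},
}


def read_expression_matrix(path, layout: str = "genes_by_samples") -> pd.DataFrame:
    """Read a delimited expression matrix (TSV or CSV by extension).

    The first column holds gene/probe identifiers and the header row sample
    ids.  Duplicate probe rows are retained for the collapse step.  Any
    non-numeric cell raises a parse error naming its location.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.empty or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty expression file")
    values = np.empty(raw.shape, dtype=np.float64)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = pd.to_numeric(raw[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = pd.to_numeric(raw[col], errors="coerce")
            row = raw.index[int(np.flatnonzero(bad.isna())[0])]
            raise ValueError(
                f"{path}: non-numeric value at gene '{row}', sample '{col}'"
            ) from None
    mat = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    if layout == "samples_by_genes":
        mat = mat.T
    elif layout != "genes_by_samples":
        raise ValueError(f"unknown layout {layout!r}")
    if not np.isfinite(mat.to_numpy()).all():
        raise ValueError(f"{path}: non-finite expression values")
    return mat


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    expr.to_csv(path, sep=sep, index_label="gene")


def read_probe_map(path) -> dict:
    """Two-column TSV mapping probe id -> gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def collapse_probes(expr: pd.DataFrame, probe_map: dict) -> pd.DataFrame:
    """Sum all probe rows mapping to the same gene.

    Probes absent from the map are dropped with a warning; an empty
    intersection of matrix probes and map entries is an error.
    """
    mapped = expr.index.isin(probe_map)
    if not mapped.any():
        raise ValueError("no probe in the matrix has a map entry")
    dropped = expr.index[~mapped]
    if len(dropped):
        logger.warning("collapse_probes: dropping %d unmapped probes", len(dropped))
    kept = expr.loc[mapped]
    genes = kept.index.map(probe_map)
    collapsed = kept.groupby(genes, sort=True).sum()
    collapsed.index.name = expr.index.name
    return collapsed


@dataclass
class Cohort:
    """Expression matrix joined to survival outcomes and covariates.

    ``clinical`` is indexed by sample id with the columns of
    `CLINICAL_COLUMNS` (optional ones may be missing/NaN); construction via
    `make_cohort` enforces the complete-RFS rule.
    """

    name: str
    expr: pd.DataFrame  # genes × samples
    clinical: pd.DataFrame  # samples × clinical columns

    @property
    def samples(self) -> list:
        return list(self.expr.columns)

    @property
    def genes(self) -> list:
        return list(self.expr.index)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def survival(self, endpoint: str = "RFS"):
        """(time, event) arrays for RFS or OS, aligned to expression columns."""
        endpoint = endpoint.upper()
        if endpoint == "RFS":
            cols = ("rfs_time_months", "rfs_event")
        elif endpoint == "OS":
            cols = ("os_time_months", "os_event")
        else:
            raise ValueError("endpoint must be 'RFS' or 'OS'")
        sub = self.clinical.loc[self.expr.columns, list(cols)]
        if sub.isna().any().any():
            raise ValueError(f"{self.name}: incomplete {endpoint} outcomes")
        return sub[cols[0]].to_numpy(float), sub[cols[1]].to_numpy(int)

    def values(self, gene: str) -> np.ndarray:
        if gene not in self.expr.index:
            raise KeyError(f"gene {gene!r} not in cohort {self.name!r}")
        return self.expr.loc[gene].to_numpy(dtype=float)


def _validate_enums(clinical: pd.DataFrame) -> None:
    for col, allowed in _ENUM_VALUES.items():
        if col not in clinical.columns:
            continue
        vals = clinical[col].dropna()
        if col in ("pt", "grade"):
            vals = vals.astype(float)
            allowed = {float(a) for a in allowed}
        bad = set(vals) - allowed
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")


def make_cohort(name: str, expr: pd.DataFrame, clinical: pd.DataFrame) -> Cohort:
    """Assemble a cohort, keeping only samples with complete expression and
    RFS (time + event) data; excluded samples are logged."""
    clinical = clinical.copy()
    _validate_enums(clinical)
    have_rfs = clinical[["rfs_time_months", "rfs_event"]].notna().all(axis=1)
    complete = [
        s for s in expr.columns if s in clinical.index and bool(have_rfs.get(s, False))
    ]
    excluded = [s for s in expr.columns if s not in complete]
    if excluded:
        logger.warning("%s: excluding %d samples with incomplete data", name, len(excluded))
    if not complete:
        raise ValueError(f"{name}: no sample has complete expression and RFS data")
    cohort = Cohort(name=name, expr=expr[complete], clinical=clinical.loc[complete])
    t, e = cohort.survival("RFS")
    if (t < 0).any():
        raise ValueError(f"{name}: negative RFS times")
    return cohort


def read_clinical_table(path) -> pd.DataFrame:
    """CSV with a sample_id column followed by the standard clinical fields."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    df = df.set_index("sample_id")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df


def load_cohort(name: str, expr_path, clinical_path, probe_map_path=None) -> Cohort:
    expr = read_expression_matrix(expr_path)
    if probe_map_path is not None:
        expr = collapse_probes(expr, read_probe_map(probe_map_path))
    return make_cohort(name, expr, read_clinical_table(clinical_path))


def zscore_per_gene(cohort: Cohort) -> Cohort:
    """Standardize each gene to mean 0, sample-sd 1 across the cohort.

    Uses the n-1 divisor.  Zero-variance genes carry no prognostic
    information and are removed (logged) rather than kept at 0.
    """
    if cohort.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    values = cohort.expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        removed = list(cohort.expr.index[~keep])
        logger.warning("%s: removing %d zero-variance genes", cohort.name, len(removed))
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
    expr = pd.DataFrame(z, index=cohort.expr.index[keep], columns=cohort.expr.columns)
    return Cohort(name=cohort.name, expr=expr, clinical=cohort.clinical)


@dataclass
class PooledCohort(Cohort):
    """Concatenation of z-scored cohorts over their shared genes; `source`
    maps each (prefixed) sample id back to its cohort of origin."""

    source: pd.Series = field(default_factory=pd.Series)


def pool_cohorts(cohorts, name: str = "pooled") -> PooledCohort:
    """Merge ≥2 per-gene z-scored cohorts over the intersection of genes.

    Sample ids are prefixed "cohortname:sampleid" so pooling is lossless
    even when ids collide across cohorts.
    """
    if len(cohorts) < 2:
        raise ValueError("pooling requires at least two cohorts")
    shared = set(cohorts[0].genes)
    for c in cohorts[1:]:
        shared &= set(c.genes)
    if not shared:
        raise ValueError("cohorts share no genes")
    genes = sorted(shared)

    expr_parts, clin_parts, src = [], [], {}
    seen: dict = {}
    for c in cohorts:
        seen[c.name] = seen.get(c.name, 0) + 1
        tag = c.name if seen[c.name] == 1 else f"{c.name}#{seen[c.name]}"
        prefixed = [f"{tag}:{s}" for s in c.samples]
        part = c.expr.loc[genes].copy()
        part.columns = prefixed
        expr_parts.append(part)
        clin = c.clinical.loc[c.samples].copy()
        clin.index = prefixed
        clin_parts.append(clin)
        src.update({p: c.name for p in prefixed})
    expr = pd.concat(expr_parts, axis=1)
    clinical = pd.concat(clin_parts, axis=0)
    return PooledCohort(
        name=name, expr=expr, clinical=clinical, source=pd.Series(src, name="source")
    )
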