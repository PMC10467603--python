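"""Genome-wide per-gene survival screen across cohorts.

For every gene, each cohort is dichotomized at the gene's maximally
selected log-rank cut-off and tested for an RFS difference.  A gene earns a
favorable/unfavorable verdict when it is significant in at least
``min_cohorts`` cohorts *and* every significant cohort agrees on the
direction of the effect; everything else is excluded.  No multiple-testing
correction is applied across genes — the cross-cohort replication rule is
the error control, so per-gene p values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._logrank import NoAdmissibleSplitError, SurvivalIndex, scan_cutpoints

__all__ = ["ScreenConfig", "GeneScreenRecord", "screen_gene", "screen_all", "screen_to_frame"]


@dataclass
class ScreenConfig:
    alpha: float = 0.05
    min_cohorts: int = 4
    minprop: float = 0.1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_cohorts < 1:
            raise ValueError("min_cohorts must be >= 1")


@dataclass
class GeneScreenRecord:
    gene: str
    per_cohort: dict = field(default_factory=dict)  # cohort -> dict(cutpoint, chi2, p, direction)
    n_significant: int = 0
    verdict: str = "excluded"  # favorable | unfavorable | excluded
    min_p: float = 1.0


def _screen_one(values, idx, cfg: ScreenConfig):
    try:
        res = scan_cutpoints(values, idx, minprop=cfg.minprop)
    except NoAdmissibleSplitError:
        return None
    return {
        "cutpoint": res["cutpoint"],
        "chi2": res["chi2"],
        "p": res["p"],
        "direction": "unfavorable" if res["z"] > 0 else "favorable",
    }


def _verdict(per_cohort, cfg: ScreenConfig):
    sig = {
        name: rec for name, rec in per_cohort.items() if rec is not None and rec["p"] < cfg.alpha
    }
    n_sig = len(sig)
    if n_sig < cfg.min_cohorts:
        return n_sig, "excluded"
    directions = {rec["direction"] for rec in sig.values()}
    if len(directions) != 1:
        return n_sig, "excluded"
    return n_sig, directions.pop()


def screen_gene(gene: str, cohorts, cfg: ScreenConfig | None = None) -> GeneScreenRecord:
    """Screen one gene across cohorts; cohorts lacking the gene count as
    non-significant.  The gene must be present in at least one cohort."""
    cfg = cfg or ScreenConfig()
    per_cohort = {}
    present = 0
    for cohort in cohorts:
        if gene not in cohort.expr.index:
            per_cohort[cohort.name] = None
            continue
        present += 1
        time, event = cohort.survival("RFS")
        idx = SurvivalIndex(time, event)
        per_cohort[cohort.name] = _screen_one(cohort.values(gene), idx, cfg)
    if present == 0:
        raise KeyError(f"gene {gene!r} found in no cohort")
    n_sig, verdict = _verdict(per_cohort, cfg)
    ps = [rec["p"] for rec in per_cohort.values() if rec is not None]
    return GeneScreenRecord(
        gene=gene,
        per_cohort=per_cohort,
        n_significant=n_sig,
        verdict=verdict,
        min_p=float(min(ps)) if ps else 1.0,
    )


def screen_all(cohorts, cfg: ScreenConfig | None = None) -> list:
    """Screen every gene in the intersection of cohort gene sets.

    Returns records ordered by the minimum per-cohort p value.  The
    survival index of each cohort is built once and shared across genes.
    """
    cfg = cfg or ScreenConfig()
    shared = set(cohorts[0].genes)
    for c in cohorts[1:]:
        shared &= set(c.genes)
    if not shared:
        raise ValueError("cohorts share no genes")
    genes = sorted(shared)

    indexes = []
    for cohort in cohorts:
        time, event = cohort.survival("RFS")
        indexes.append(SurvivalIndex(time, event))

    records = []
    for gene in genes:
        per_cohort = {}
        for cohort, idx in zip(cohorts, indexes):
            per_cohort[cohort.name] = _screen_one(cohort.values(gene), idx, cfg)
        n_sig, verdict = _verdict(per_cohort, cfg)
        ps = [rec["p"] for rec in per_cohort.values() if rec is not None]
        records.append(
            GeneScreenRecord(
                gene=gene,
                per_cohort=per_cohort,
                n_significant=n_sig,
                verdict=verdict,
                min_p=float(min(ps)) if ps else 1.0,
            )
        )
    records.sort(key=lambda r: (r.min_p, r.gene))
    return records


def screen_to_frame(records) -> pd.DataFrame:
    """Flatten screen records to a writable table (one row per gene)."""
    rows = []
    for r in records:
        row = {"gene": r.gene, "verdict": r.verdict, "n_significant": r.n_significant,
               "min_p": r.min_p}
        for cohort, rec in r.per_cohort.items():
            if rec is None:
                row[f"{cohort}:p"] = np.nan
                continue
            row[f"{cohort}:p"] = rec["p"]
            row[f"{cohort}:cutpoint"] = rec["cutpoint"]
            row[f"{cohort}:direction"] = rec["direction"]
        rows.append(row)
    return pd.DataFrame(rows)
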