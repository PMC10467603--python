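"""Synthetic multi-cohort expression + survival data with planted
prognostic structure, and NanoString-style raw counts.

The expression model plants a coherent "risk program": a latent per-patient
factor F ~ N(0,1) on which every prognostic gene loads with ±sqrt(r)
(positive for unfavorable genes, negative for favorable ones), the rest of
each gene being independent noise.  Relapse hazards are proportional and
act on the planted genes' own (standardized) expression values,

    h_i = lambda0 * u_i * exp(sum_g beta_g z_ig + beta_pT * 1[pT4_i]),

with generative coefficients beta_g = s_g * effect / (1 + (k-1) r) for k
planted genes of sign s_g, so that each planted gene's MARGINAL log hazard
ratio per expression SD equals the configured effect size exactly, while
the co-expression concentrates the summed linear predictor to a
biologically plausible spread (sd ≈ effect * sqrt(k(1+(k-1)r)) / (1+(k-1)r))
instead of the absurd effect*sqrt(k) an independent-gene sum would give.
Because the hazard sees each gene's idiosyncratic component, every planted
gene carries signal of its own — the property the signature-refinement
stage exists to exploit.  A lognormal frailty u_i is shared between relapse
and death; overall survival uses an attenuated linear predictor through the
same frailty.
Event times are exponential given the hazard; censoring combines an
administrative horizon with uniform early dropout.  Cohort batch effects
are per-gene location shifts plus a cohort-wide scale factor, removable by
per-gene z-scoring.

The NanoString block generates negative-binomial endogenous counts under
sample-specific lane factors, a fixed positive-control dilution series,
high stable housekeeping genes, planted low-expression genes (mean < 10)
and planted dispersed outlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohorts import make_cohort
from .nanostring import DEFAULT_HOUSEKEEPING, RawCountTable

__all__ = ["SimConfig", "PlantedTruth", "simulate_cohort", "simulate_training_suite", "simulate_nanostring"]


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the multi-cohort design the pipeline targets: six
    cohorts of 150 stage II tumors, ~520 genes of which 10+10 carry a
    relapse effect of |log-HR| = 0.8 per expression SD, exponential
    baseline hazard 0.004/month (≈38% relapse within the 120-month
    administrative horizon before dropout), and 20% uniform early dropout.
    """

    n_cohorts: int = 6
    n_samples: int = 150
    n_genes: int = 520
    n_unfavorable: int = 10
    n_favorable: int = 10
    effect_size: float = 0.8  # marginal |log-HR| per expression SD
    latent_loading: float = 0.25  # r: share of planted-gene variance on the risk factor
    baseline_hazard: float = 0.004  # relapse events per month
    os_baseline_hazard: float = 0.002
    os_attenuation: float = 0.5
    frailty_sd: float = 0.3
    horizon: float = 120.0  # administrative censoring, months
    dropout_rate: float = 0.2  # fraction with uniform early dropout
    batch_loc_sd: float = 0.5  # per-cohort per-gene location shift SD
    batch_scale_sd: float = 0.2  # lognormal SD of the cohort-wide scale
    pt4_prevalence: float = 0.2
    pt_log_hazard: float = 0.8
    # NanoString block
    ns_n_samples: int = 205  # validation-cohort scale
    ns_n_endogenous: int = 52
    ns_n_low: int = 9
    ns_n_housekeeping: int = 6
    ns_n_positive: int = 6
    ns_lane_sd: float = 0.15  # lognormal SD of lane factors
    ns_nb_size: float = 20.0  # negative-binomial size (dispersion = 1/size)
    ns_outliers: int = 5
    ns_outlier_sd: float = 1.0  # per-gene lognormal noise SD in outlier samples
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_cohorts, self.n_samples, self.n_genes, self.n_unfavorable,
            self.n_favorable, self.ns_n_samples, self.ns_n_endogenous,
            self.ns_n_low, self.ns_n_housekeeping, self.ns_n_positive,
            self.ns_outliers,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if self.n_unfavorable + self.n_favorable > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")
        if not 0 < self.latent_loading <= 1:
            raise ValueError("latent_loading must be in (0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")


@dataclass
class PlantedTruth:
    directions: dict  # gene -> 'unfavorable' / 'favorable' for planted genes
    effect_size: float
    linear_predictor: dict = field(default_factory=dict)  # cohort -> per-sample lp


def _gene_names(cfg: SimConfig):
    unfav = [f"UNFAV{i:03d}" for i in range(cfg.n_unfavorable)]
    fav = [f"FAV{i:03d}" for i in range(cfg.n_favorable)]
    null = [f"NULL{i:04d}" for i in range(cfg.n_genes - len(unfav) - len(fav))]
    return unfav, fav, null


def _draw_survival(rng, hazard, horizon, dropout_rate):
    t_event = rng.exponential(1.0 / hazard)
    censor = np.full(hazard.size, horizon)
    drop = rng.random(hazard.size) < dropout_rate
    censor[drop] = rng.uniform(0.0, horizon, size=int(drop.sum()))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    return time, event


def simulate_cohort(cfg: SimConfig, cohort_index: int = 0):
    """One cohort plus its planted truth.

    The cohort's RNG stream is spawned deterministically from the master
    seed and the cohort index, so cohorts are independent yet reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed).spawn(cfg.n_cohorts + 1)[cohort_index]
    rng = np.random.default_rng(ss)
    name = f"sim{cohort_index}"
    unfav, fav, null = _gene_names(cfg)
    genes = unfav + fav + null
    n = cfg.n_samples
    r = cfg.latent_loading

    factor = rng.standard_normal(n)
    z = rng.standard_normal((len(genes), n))
    for i, g in enumerate(unfav):
        z[i] = np.sqrt(r) * factor + np.sqrt(1 - r) * z[i]
    for j, g in enumerate(fav):
        i = len(unfav) + j
        z[i] = -np.sqrt(r) * factor + np.sqrt(1 - r) * z[i]

    loc = rng.normal(0.0, cfg.batch_loc_sd, size=(len(genes), 1))
    scale = float(rng.lognormal(0.0, cfg.batch_scale_sd))
    expr = pd.DataFrame(
        loc + scale * z, index=genes, columns=[f"{name}S{i:04d}" for i in range(n)]
    )

    pt4 = rng.random(n) < cfg.pt4_prevalence
    k = len(unfav) + len(fav)
    lp = cfg.pt_log_hazard * pt4.astype(float)
    if k:
        # beta_g chosen so each gene's marginal log-HR per SD = effect_size
        beta = cfg.effect_size / (1.0 + (k - 1) * r)
        signs = np.r_[np.ones(len(unfav)), -np.ones(len(fav))]
        lp = lp + beta * (signs[:, None] * z[:k]).sum(axis=0)
    frailty = rng.lognormal(0.0, cfg.frailty_sd, size=n)

    rfs_t, rfs_e = _draw_survival(
        rng, cfg.baseline_hazard * frailty * np.exp(lp), cfg.horizon, cfg.dropout_rate
    )
    os_t, os_e = _draw_survival(
        rng,
        cfg.os_baseline_hazard * frailty * np.exp(cfg.os_attenuation * lp),
        cfg.horizon,
        cfg.dropout_rate,
    )

    clinical = pd.DataFrame(
        {
            "rfs_time_months": rfs_t,
            "rfs_event": rfs_e,
            "os_time_months": os_t,
            "os_event": os_e,
            "pt": np.where(pt4, 4, 3),
            "grade": rng.choice([1, 2, 3], size=n, p=[0.1, 0.55, 0.35]),
            "msi": rng.choice(["MSS", "MSI"], size=n, p=[0.85, 0.15]),
            "kras": rng.choice(["wt", "mut"], size=n, p=[0.6, 0.4]),
            "age": np.round(rng.normal(69.0, 10.0, size=n), 1),
            "sex": rng.choice(["male", "female"], size=n),
        },
        index=expr.columns,
    )
    cohort = make_cohort(name, expr, clinical)
    truth = PlantedTruth(
        directions={**{g: "unfavorable" for g in unfav}, **{g: "favorable" for g in fav}},
        effect_size=cfg.effect_size,
        linear_predictor={name: lp},
    )
    return cohort, truth


def simulate_training_suite(cfg: SimConfig):
    """List of independent cohorts sharing one planted truth."""
    cohorts = []
    truth = PlantedTruth(directions={}, effect_size=cfg.effect_size)
    for i in range(cfg.n_cohorts):
        cohort, t = simulate_cohort(cfg, i)
        cohorts.append(cohort)
        truth.directions = t.directions
        truth.linear_predictor.update(t.linear_predictor)
    return cohorts, truth


@dataclass
class NanoStringTruth:
    abundances: pd.Series  # expected endogenous counts at lane factor 1
    low_genes: list
    outlier_samples: list
    lane_factors: pd.Series


def simulate_nanostring(cfg: SimConfig):
    """NanoString-style raw count table with planted QC structure."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(cfg.n_cohorts + 1)[-1])
    n = cfg.ns_n_samples
    samples = [f"NS{i:03d}" for i in range(n)]

    endo = [f"GENE{i:03d}" for i in range(cfg.ns_n_endogenous)]
    low = [f"LOWG{i:02d}" for i in range(cfg.ns_n_low)]
    hk = list(DEFAULT_HOUSEKEEPING[: cfg.ns_n_housekeeping])
    pos = [f"POS_{chr(65 + i)}" for i in range(cfg.ns_n_positive)]

    mu_endo = rng.lognormal(np.log(300.0), 0.8, size=cfg.ns_n_endogenous)
    mu_endo = np.maximum(mu_endo, 30.0)  # keep planted-low and test genes separated
    mu_low = rng.uniform(0.5, 6.0, size=cfg.ns_n_low)
    mu_hk = rng.lognormal(np.log(800.0), 0.2, size=len(hk))
    mu_pos = 32.0 * 4.0 ** np.arange(cfg.ns_n_positive - 1, -1, -1) / 4.0  # dilution series

    lane = rng.lognormal(0.0, cfg.ns_lane_sd, size=n)
    outliers = samples[:: max(1, n // max(cfg.ns_outliers, 1))][: cfg.ns_outliers]
    outlier_mask = np.isin(samples, outliers)

    def nb(mean):
        size = cfg.ns_nb_size
        return rng.negative_binomial(size, size / (size + mean))

    mu = np.concatenate([mu_endo, mu_low, mu_hk, mu_pos])
    probes = endo + low + hk + pos
    expected = mu[:, None] * lane[None, :]
    # dispersed outlier samples: extra per-gene multiplicative noise
    noise = np.ones((len(probes), n))
    if outlier_mask.any():
        noise[:, outlier_mask] = rng.lognormal(
            0.0, cfg.ns_outlier_sd, size=(len(probes), int(outlier_mask.sum()))
        )
    counts = nb(expected * noise).astype(float)

    table = RawCountTable(
        counts=pd.DataFrame(counts, index=probes, columns=samples),
        probe_class=pd.Series(
            ["endogenous"] * (len(endo) + len(low))
            + ["housekeeping"] * len(hk)
            + ["positive_control"] * len(pos),
            index=probes,
        ),
        hk_genes=tuple(hk),
    )
    truth = NanoStringTruth(
        abundances=pd.Series(np.concatenate([mu_endo, mu_low]), index=endo + low),
        low_genes=low,
        outlier_samples=list(outliers),
        lane_factors=pd.Series(lane, index=samples),
    )
    return table, truth


def config_to_dict(cfg: SimConfig) -> dict:
    return asdict(cfg)
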