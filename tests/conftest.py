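import numpy as np
import pandas as pd
import pytest

from prognosig.cohorts import make_cohort, zscore_per_gene
from prognosig.simdata import SimConfig, simulate_training_suite


@pytest.fixture
def rng():
    return np.random.default_rng(20230830)


def tiny_cohort(seed=0, n=60, genes=("G1", "G2", "G3"), name="tiny", effect=1.0):
    """Small hand-rolled cohort: G1 prognostic, the rest noise."""
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame(
        rng.normal(size=(len(genes), n)), index=list(genes),
        columns=[f"s{i:03d}" for i in range(n)],
    )
    lp = effect * expr.iloc[0].to_numpy()
    t_event = rng.exponential(60.0 / np.exp(lp))
    censor = np.minimum(rng.exponential(150.0, size=n), 120.0)
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(int)
    clinical = pd.DataFrame(
        {
            "rfs_time_months": time,
            "rfs_event": event,
            "os_time_months": time,
            "os_event": event,
            "pt": rng.choice([3, 4], size=n),
            "grade": rng.choice([1, 2, 3], size=n),
            "msi": rng.choice(["MSS", "MSI"], size=n),
            "kras": rng.choice(["wt", "mut"], size=n),
            "age": rng.normal(68, 8, size=n).round(1),
            "sex": rng.choice(["male", "female"], size=n),
        },
        index=expr.columns,
    )
    return make_cohort(name, expr, clinical)


@pytest.fixture
def small_cohort():
    return tiny_cohort()


@pytest.fixture(scope="session")
def small_suite():
    """Three modest cohorts with 2+2 planted genes, z-scored, plus truth."""
    cfg = SimConfig(
        seed=7, n_cohorts=3, n_samples=80, n_genes=30, n_unfavorable=2, n_favorable=2
    )
    cohorts, truth = simulate_training_suite(cfg)
    return [zscore_per_gene(c) for c in cohorts], truth
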