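"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from txnet.synthetic import SimulationConfig, simulate_counts


def groups_of(samples: pd.DataFrame) -> pd.Series:
    return pd.Series(samples["group"].values, index=samples["sample"].values)


@pytest.fixture(scope="session")
def null_dataset():
    """Global-null simulation: 2000 genes, 5 reps/group, alpha=0.1."""
    cfg = SimulationConfig(
        n_genes=2000, n_reps_per_group=5, de_fraction=0.0, effect_log2=0.0,
        dispersion=0.1, seed=7,
    )
    counts, samples, truth = simulate_counts(cfg)
    return counts, groups_of(samples), truth


@pytest.fixture(scope="session")
def planted_dataset():
    """10% planted DE at |log2FC| = 2, baseline means >= 100, 5 reps/group."""
    cfg = SimulationConfig(
        n_genes=2000, n_reps_per_group=5, de_fraction=0.1, effect_log2=2.0,
        dispersion=0.1, mean_log_range=(np.log(100.0), np.log(5000.0)), seed=7,
    )
    counts, samples, truth = simulate_counts(cfg)
    return counts, groups_of(samples), truth
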