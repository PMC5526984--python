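import numpy as np
import pandas as pd
import pytest

from crosslimb.sim_data import PlantedEffect, SimConfig, simulate_gene_counts


@pytest.fixture
def small_joined():
    """A 300-gene joined two-species count matrix with one planted gene."""
    cfg = SimConfig(n_genes=300, seed=42, planted=[PlantedEffect(0, 4.0)])
    emu, chick, samples, truth = simulate_gene_counts(cfg)
    return pd.concat([emu, chick], axis=1), samples, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_joined(cfg: SimConfig):
    emu, chick, samples, truth = simulate_gene_counts(cfg)
    return pd.concat([emu, chick], axis=1), samples, truth
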