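import numpy as np
import pandas as pd
import pytest

from prrlayers import simulate as sim
from prrlayers.normalization import tmm_normalized_tpm


@pytest.fixture(scope="session")
def small_experiment():
    """One modest synthetic run shared by read-only tests."""
    cfg = sim.SimulationConfig(n_genes=2000, seed=42, n_responsive=80)
    design = sim.simulate_design(cfg.n_individuals, cfg.dropout_samples)
    exp = sim.simulate_counts(cfg, design)
    return cfg, exp


@pytest.fixture(scope="session")
def small_normalized(small_experiment):
    cfg, exp = small_experiment
    norm, factors = tmm_normalized_tpm(exp.counts, exp.lengths)
    return norm, factors


def nb_counts(rng, mu, dispersion, n_samples):
    """Gamma-Poisson draws, mu a vector, for ad-hoc test matrices."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu[:, None], size=(len(mu), n_samples))
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu[:, None] * dispersion, size=(len(mu), n_samples))
    return rng.poisson(lam)
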