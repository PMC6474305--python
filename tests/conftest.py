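import logging

import numpy as np
import pandas as pd
import pytest

import mycocontext as mc

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def toy_dataset() -> mc.AnalysisDataset:
    """4 samples x 3 OTUs, hand-written, both seasons and two sites."""
    samples = pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4"],
            "site": ["a", "a", "b", "b"],
            "region": ["r1", "r1", "r2", "r2"],
            "season": ["summer", "winter", "summer", "winter"],
            "salinity": [30.0, 28.0, 15.0, 17.0],
            "ph": [6.5, 6.8, 7.0, 6.9],
            "moisture": [50.0, 55.0, 60.0, 52.0],
            "plant_richness": [4, 6, 5, 7],
            "root_biomass": [2.0, 3.1, 1.5, 2.4],
            "cover_herb": [10.0, 15.0, 20.0, 12.0],
            "cover_shrub": [40.0, 35.0, 5.0, 8.0],
            "cover_grass": [20.0, 25.0, 50.0, 45.0],
            "cover_sedge": [5.0, 4.0, 10.0, 12.0],
            "cover_rush": [1.0, 2.0, 5.0, 6.0],
        }
    )
    counts = pd.DataFrame(
        [[0, 3, 1], [2, 0, 0], [5, 1, 2], [1, 1, 1]],
        index=["S1", "S2", "S3", "S4"],
        columns=["otu1", "otu2", "otu3"],
    )
    guilds = pd.Series(
        {"otu1": "saprotroph", "otu2": "symbiotroph"}, name="trophic_group"
    )
    return mc.AnalysisDataset(samples=samples, counts=counts, guilds=guilds)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared across tests (seed fixed)."""
    cfg = mc.SimulationConfig(n_otus=80, quadrats_per_site_season=8, seed=42)
    return mc.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def default_sim():
    """Full study layout (264 samples), moderate community size."""
    cfg = mc.SimulationConfig(n_otus=150, seed=7)
    return mc.simulate_dataset(cfg)


def two_group_mixture_data(seed: int, n_otu: int = 60, n_samp: int = 50):
    """Well-separated two-archetype NB data with known truth."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {"x1": rng.normal(size=n_samp), "x2": rng.normal(size=n_samp)}
    )
    beta_true = np.array([[1.0, -0.5], [-0.3, 0.8]])  # gap >= 1 on the log scale
    pi_true = np.array([0.5, 0.5])
    groups = rng.choice(2, size=n_otu, p=pi_true)
    alpha = rng.normal(2.5, 0.8, size=n_otu)
    theta = np.array([1.5, 1.5])
    eta = alpha[:, None] + beta_true[groups] @ X.to_numpy().T
    mean = np.exp(eta)
    th = theta[groups][:, None]
    Y = rng.negative_binomial(th, th / (th + mean))
    table = pd.DataFrame(Y.T, columns=[f"O{i:03d}" for i in range(n_otu)])
    return table, X, groups, beta_true, pi_true, theta
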