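"""Synthetic salt-marsh datasets with known generative truth.

The generator emulates the study design the pipeline targets: two
regions x three sites x two seasons x 22 quadrats (264 samples),
heterogeneous sequencing depths, region-structured covariates (one
region more saline and more variable, shrub-dominated; the other
fresher and grass/sedge-dominated), and NB-distributed OTU counts whose
log-means respond to covariates through ecogroup-shared coefficient
vectors:

    y_ij ~ NB(mean = L_j * exp(alpha_i + x_j' beta_g(i)), theta_g(i))

where g(i) is OTU i's true ecogroup, L_j the target library size and
x_j the standardised covariate row.  Richness-environment relationships
therefore arise only through OTU-level responses (occupancy follows
from NB zeros); nothing is injected into richness directly.  Guild
labels are drawn per OTU from a group-specific distribution, with most
OTUs unassigned, so ecogroup and trophic group are statistically
associated when the association matrix says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datasets import AnalysisDataset, TROPHIC_GROUPS, UNASSIGNED

#: covariates OTU responses act on (standardised internally)
RESPONSE_TERMS = [
    "season_winter",
    "salinity",
    "ph",
    "moisture",
    "plant_richness",
    "root_biomass",
    "cover_shrub",
    "cover_grass",
]

_DEFAULT_BETA = np.array(
    [
        # winter  salin   ph   moist  plant_r  biomass  shrub  grass
        [0.6, -0.4, 0.0, 0.1, 0.3, 0.0, -0.2, 0.1],
        [-0.5, 0.3, -0.3, 0.0, 0.0, 0.4, 0.2, -0.1],
        [0.0, 0.5, 0.2, -0.3, -0.4, 0.1, -0.5, 0.0],
        [0.3, 0.0, -0.4, 0.4, 0.1, -0.3, 0.0, 0.3],
        [-0.2, -0.3, 0.3, 0.0, 0.4, 0.2, 0.3, -0.4],
        [0.1, 0.2, 0.0, -0.2, -0.2, -0.4, 0.1, 0.4],
    ]
)

#: rows = true ecogroup, cols = the six trophic groups; a matched-guild
#: probability of 0.5 (rest uniform) gives a clearly detectable association
_DEFAULT_GUILD_ASSOC = np.full((6, 6), 0.1) + np.eye(6) * 0.4


@dataclass
class SimulationConfig:
    """Study-design and generative parameters (defaults = study layout)."""

    n_regions: int = 2
    sites_per_region: int = 3
    quadrats_per_site_season: int = 22
    seasons: tuple[str, str] = ("summer", "winter")
    region_names: tuple[str, ...] = ("region_a", "region_b")
    # abiotic generators: per-region (mean, sd) and per-site mean shifts
    salinity: dict = field(
        default_factory=lambda: {
            "region_mean": (32.0, 16.0),
            "region_sd": (6.0, 3.0),
            "site_shift": (-3.0, 0.0, 3.0),
        }
    )
    ph: dict = field(
        default_factory=lambda: {
            "region_mean": (6.8, 6.9),
            "region_sd": (0.35, 0.35),
            "site_shift": (-0.2, 0.0, 0.2),
        }
    )
    moisture: dict = field(
        default_factory=lambda: {
            "region_mean": (55.0, 52.0),
            "region_sd": (9.0, 9.0),
            "site_shift": (-4.0, 0.0, 4.0),
        }
    )
    #: Dirichlet weights over (herb, shrub, grass, sedge, rush) per region
    cover_weights: tuple = ((2.5, 5.0, 1.5, 0.7, 0.3), (2.0, 0.4, 4.5, 2.2, 0.9))
    total_cover_mean: float = 80.0
    total_cover_sd: float = 12.0  # per-quadrat totals vary: covers are not closed to 100
    plant_richness_rate: float = 6.0
    root_biomass_logmean: float = 1.0
    root_biomass_logsd: float = 0.5
    # library sizes, log-normal
    library_logmean: float = np.log(20_000.0)
    library_logsd: float = 0.45
    # community
    n_otus: int = 300
    G_true: int = 6
    beta_true: np.ndarray = field(default_factory=lambda: _DEFAULT_BETA.copy())
    pi_true: np.ndarray = field(default_factory=lambda: np.full(6, 1 / 6))
    theta_true: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 1.5, 0.8, 1.2, 2.0, 0.6])
    )
    alpha_sd: float = 2.5  # heavy tail: many rare OTUs, so occupancy responds to covariates
    guild_association: np.ndarray = field(default_factory=lambda: _DEFAULT_GUILD_ASSOC.copy())
    p_unassigned: float = 0.55
    seed: int = 0

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.pi_true = np.asarray(self.pi_true, dtype=float)
        self.theta_true = np.asarray(self.theta_true, dtype=float)
        self.guild_association = np.asarray(self.guild_association, dtype=float)
        if self.beta_true.shape != (self.G_true, len(RESPONSE_TERMS)):
            raise ValueError(
                f"beta_true must be {self.G_true} x {len(RESPONSE_TERMS)}"
            )
        if abs(self.pi_true.sum() - 1.0) > 1e-8 or (self.pi_true < 0).any():
            raise ValueError("pi_true must be a probability vector")
        if (self.theta_true <= 0).any():
            raise ValueError("theta_true must be positive")
        if not (0 <= self.p_unassigned < 1):
            raise ValueError("p_unassigned must be in [0, 1)")
        rs = self.guild_association.sum(axis=1)
        if (self.guild_association < 0).any() or not np.allclose(rs, 1.0):
            raise ValueError("guild_association rows must be probability vectors")
        for cov in (self.salinity, self.ph, self.moisture):
            if any(s <= 0 for s in cov["region_sd"]):
                raise ValueError("covariate SDs must be positive")

    def homogeneous(self) -> "SimulationConfig":
        """A copy with identical covariate generators in every region/site.

        Useful as the null condition for transfer calibration: all sites
        are draws from one global generative process, regions become
        arbitrary labels.
        """
        import copy

        cfg = copy.deepcopy(self)
        for cov in (cfg.salinity, cfg.ph, cfg.moisture):
            m = float(np.mean(cov["region_mean"]))
            s = float(np.mean(cov["region_sd"]))
            cov["region_mean"] = (m,) * cfg.n_regions
            cov["region_sd"] = (s,) * cfg.n_regions
            cov["site_shift"] = (0.0,) * cfg.sites_per_region
        w = tuple(float(np.mean([wts[i] for wts in cfg.cover_weights]))
                  for i in range(5))
        cfg.cover_weights = (w,) * cfg.n_regions
        return cfg


@dataclass
class SyntheticTruth:
    """Ground truth bundled with every simulated dataset."""

    ecogroup: np.ndarray  # true group index per OTU (0-based)
    beta_true: np.ndarray
    pi_true: np.ndarray
    theta_true: np.ndarray
    alpha: np.ndarray
    guild_association: np.ndarray
    config: SimulationConfig

    def to_dict(self) -> dict:
        d = {
            "ecogroup": self.ecogroup.tolist(),
            "beta_true": self.beta_true.tolist(),
            "pi_true": self.pi_true.tolist(),
            "theta_true": self.theta_true.tolist(),
            "alpha": self.alpha.tolist(),
            "guild_association": self.guild_association.tolist(),
        }
        return d


def _norm(rng, mean, sd, size):
    return rng.normal(mean, sd, size)


def simulate_covariates(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Site-structured covariate table (one row per quadrat sample)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    sid = 0
    for r in range(config.n_regions):
        region = config.region_names[r]
        for s in range(config.sites_per_region):
            site = f"{region}_site{s + 1}"
            for season in config.seasons:
                for _ in range(config.quadrats_per_site_season):
                    sid += 1
                    total = float(
                        np.clip(
                            rng.normal(config.total_cover_mean, config.total_cover_sd),
                            20.0,
                            100.0,
                        )
                    )
                    covers = rng.dirichlet(config.cover_weights[r]) * total
                    rows.append(
                        {
                            "sample_id": f"S{sid:04d}",
                            "site": site,
                            "region": region,
                            "season": season,
                            "salinity": max(
                                0.0,
                                rng.normal(
                                    config.salinity["region_mean"][r]
                                    + config.salinity["site_shift"][s],
                                    config.salinity["region_sd"][r],
                                ),
                            ),
                            "ph": float(
                                np.clip(
                                    rng.normal(
                                        config.ph["region_mean"][r]
                                        + config.ph["site_shift"][s],
                                        config.ph["region_sd"][r],
                                    ),
                                    3.0,
                                    10.0,
                                )
                            ),
                            "moisture": float(
                                np.clip(
                                    rng.normal(
                                        config.moisture["region_mean"][r]
                                        + config.moisture["site_shift"][s],
                                        config.moisture["region_sd"][r],
                                    ),
                                    1.0,
                                    100.0,
                                )
                            ),
                            "plant_richness": int(
                                rng.poisson(config.plant_richness_rate)
                            ),
                            "root_biomass": float(
                                rng.lognormal(
                                    config.root_biomass_logmean,
                                    config.root_biomass_logsd,
                                )
                            ),
                            "cover_herb": covers[0],
                            "cover_shrub": covers[1],
                            "cover_grass": covers[2],
                            "cover_sedge": covers[3],
                            "cover_rush": covers[4],
                        }
                    )
    return pd.DataFrame(rows)


def _response_matrix(samples: pd.DataFrame) -> np.ndarray:
    """Standardised covariate rows the OTU responses act on."""
    X = np.column_stack(
        [
            (samples["season"] == "winter").to_numpy(dtype=float),
            samples["salinity"].to_numpy(dtype=float),
            samples["ph"].to_numpy(dtype=float),
            samples["moisture"].to_numpy(dtype=float),
            samples["plant_richness"].to_numpy(dtype=float),
            samples["root_biomass"].to_numpy(dtype=float),
            samples["cover_shrub"].to_numpy(dtype=float),
            samples["cover_grass"].to_numpy(dtype=float),
        ]
    )
    for j in range(1, X.shape[1]):  # leave the winter dummy on its own scale
        sd = X[:, j].std()
        X[:, j] = (X[:, j] - X[:, j].mean()) / (sd if sd > 0 else 1.0)
    return X


def draw_truth(config: SimulationConfig, rng) -> SyntheticTruth:
    groups = rng.choice(config.G_true, size=config.n_otus, p=config.pi_true)
    alpha = rng.normal(0.0, config.alpha_sd, size=config.n_otus)
    alpha = alpha - np.log(np.exp(alpha).sum())  # sum exp(alpha) = 1
    return SyntheticTruth(
        ecogroup=groups,
        beta_true=config.beta_true,
        pi_true=config.pi_true,
        theta_true=config.theta_true,
        alpha=alpha,
        guild_association=config.guild_association,
        config=config,
    )


def simulate_counts(
    samples: pd.DataFrame, truth: SyntheticTruth, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """NB count table: mean = L_j * exp(alpha_i + x_j' beta_g(i))."""
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    X = _response_matrix(samples)
    n = len(samples)
    L = rng.lognormal(config.library_logmean, config.library_logsd, size=n)
    eta = truth.alpha[:, None] + truth.beta_true[truth.ecogroup] @ X.T
    mean = L[None, :] * np.exp(eta)
    if np.nanmax(mean) > 1e7:
        raise ValueError(
            "simulated NB mean exceeds 1e7; reduce alpha_sd or beta_true"
        )
    theta = truth.theta_true[truth.ecogroup][:, None]
    counts = rng.negative_binomial(theta, theta / (theta + mean))
    otu_ids = [f"OTU{i + 1:04d}" for i in range(config.n_otus)]
    df = pd.DataFrame(
        counts.T, index=samples["sample_id"].to_numpy(), columns=otu_ids
    )
    # a sample with zero reads everywhere is unusable; re-seed one read
    zero = df.sum(axis=1) == 0
    if zero.any():
        df.loc[zero, otu_ids[0]] = 1
    return df


def draw_guilds(truth: SyntheticTruth, config: SimulationConfig, rng, otu_ids) -> pd.Series:
    labels = []
    for g in truth.ecogroup:
        if rng.random() < config.p_unassigned:
            labels.append(UNASSIGNED)
        else:
            labels.append(
                TROPHIC_GROUPS[rng.choice(6, p=config.guild_association[g])]
            )
    return pd.Series(labels, index=otu_ids, name="trophic_group")


def simulate_dataset(config: SimulationConfig) -> tuple[AnalysisDataset, SyntheticTruth]:
    """Full bundle: covariates, counts, guilds and the truth record."""
    rng = np.random.default_rng(config.seed)
    samples = simulate_covariates(config, rng)
    truth = draw_truth(config, rng)
    counts = simulate_counts(samples, truth, config, rng)
    guilds = draw_guilds(truth, config, rng, list(counts.columns))
    ds = AnalysisDataset(samples=samples, counts=counts, guilds=guilds)
    return ds, truth
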