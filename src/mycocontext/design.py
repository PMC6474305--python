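"""Abiotic and biotic design matrices at site, region and overall scales.

Two variable sets are compared throughout the pipeline:

* abiotic — season, porewater salinity, pH, soil moisture, plus a site
  factor when data are pooled at the regional or overall scale;
* biotic — plant species richness, total root biomass and percentage
  cover of herbs/forbs, shrubs, grasses, sedges and rushes.

Library size enters richness models as log(library size), the first
covariate after the intercept; abundance models move it to an offset
with coefficient fixed at 1 (counts proportional to sequencing depth).

Categorical terms use treatment contrasts with the lexicographically
first level as reference, so ``season`` is encoded as a winter dummy
(positive coefficients mean higher in winter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import AnalysisDataset

logger = logging.getLogger(__name__)

ABIOTIC_TERMS = ["season", "salinity", "ph", "moisture"]
BIOTIC_TERMS = [
    "plant_richness",
    "root_biomass",
    "cover_herb",
    "cover_shrub",
    "cover_grass",
    "cover_sedge",
    "cover_rush",
]


@dataclass(frozen=True)
class VariableSet:
    name: str  # "abiotic" or "biotic"
    terms: tuple[str, ...] = ()
    include_site_factor: bool = False  # site enters abiotic models when pooling

    def __post_init__(self):
        if self.name not in ("abiotic", "biotic"):
            raise ValueError("variable set must be 'abiotic' or 'biotic'")
        if not self.terms:
            object.__setattr__(
                self,
                "terms",
                tuple(ABIOTIC_TERMS if self.name == "abiotic" else BIOTIC_TERMS),
            )
        allowed = set(ABIOTIC_TERMS if self.name == "abiotic" else BIOTIC_TERMS)
        bad = set(self.terms) - allowed
        if bad:
            raise ValueError(f"term(s) {sorted(bad)} not allowed in {self.name} set")


ABIOTIC = VariableSet("abiotic")
BIOTIC = VariableSet("biotic")


@dataclass(frozen=True)
class ScaleSpec:
    """An analysis scope: one site, one region, or all data pooled."""

    level: str  # "site" | "region" | "overall"
    unit: str = "all"

    def __post_init__(self):
        if self.level not in ("site", "region", "overall"):
            raise ValueError(f"unknown scale level {self.level!r}")

    def select(self, samples: pd.DataFrame) -> np.ndarray:
        if self.level == "overall":
            return np.ones(len(samples), dtype=bool)
        mask = (samples[self.level] == self.unit).to_numpy()
        if not mask.any():
            raise ValueError(f"no samples for {self.level} {self.unit!r}")
        return mask

    def label(self) -> str:
        return "overall" if self.level == "overall" else str(self.unit)


def all_scales(dataset: AnalysisDataset) -> list[ScaleSpec]:
    """Site, region and overall scopes in deterministic order."""
    scales = [ScaleSpec("site", s) for s in dataset.sites]
    scales += [ScaleSpec("region", r) for r in dataset.regions]
    scales.append(ScaleSpec("overall"))
    return scales


def _dummy_columns(values: pd.Series, prefix: str) -> pd.DataFrame:
    levels = sorted(values.unique())
    cols = {}
    for lev in levels[1:]:  # treatment contrasts, first level = reference
        cols[f"{prefix}[{lev}]"] = (values == lev).astype(float).to_numpy()
    return pd.DataFrame(cols, index=values.index)


def build_design(
    samples: pd.DataFrame,
    library_size: pd.Series,
    vset: VariableSet,
    scale: ScaleSpec,
    mode: str = "richness",
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Assemble the design matrix (and offset) for one scope.

    Returns ``(X, offset)``: in richness mode the offset is None and
    log(library size) is the first covariate after the intercept; in
    abundance mode the same covariates are returned with
    log(library size) as the offset instead.  Terms constant within the
    scope (e.g. the site factor at site scale) are dropped with a
    warning.
    """
    if mode not in ("richness", "abundance"):
        raise ValueError("mode must be 'richness' or 'abundance'")
    mask = scale.select(samples)
    sub = samples.loc[mask]
    lib = library_size.loc[sub["sample_id"].to_numpy()].to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size in scope")
    log_lib = np.log(lib)

    parts = [pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)]
    if mode == "richness":
        parts.append(pd.DataFrame({"log_library": log_lib}, index=sub.index))

    if vset.name == "abiotic" and (vset.include_site_factor or scale.level != "site"):
        if scale.level == "site":
            logger.warning("site factor constant at site scale; dropped")
        elif sub["site"].nunique() > 1:
            parts.append(_dummy_columns(sub["site"], "site"))
        else:
            logger.warning("site factor constant within scope %s; dropped", scale.label())

    for term in vset.terms:
        if term == "season":
            if sub["season"].nunique() > 1:
                parts.append(_dummy_columns(sub["season"], "season"))
            else:
                logger.warning("season constant within scope %s; dropped", scale.label())
        else:
            col = sub[term].astype(float)
            if col.nunique() <= 1:
                logger.warning("term %s constant within scope %s; dropped", term, scale.label())
            else:
                parts.append(col.to_frame(term))

    X = pd.concat(parts, axis=1)
    offset = log_lib if mode == "abundance" else None
    return X, offset
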