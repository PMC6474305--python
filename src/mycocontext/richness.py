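"""Richness models per scale and the abiotic-vs-biotic comparison table.

OTU richness is modelled with NB GLMs at three nested scopes — each
site, each region (sites pooled), and all data pooled — once with the
abiotic variable set and once with the biotic set.  Models are compared
by AIC and adjusted D²; the comparison table mirrors the classic
site/region/overall layout with one AIC and one adjusted-D² column per
variable set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datasets import AnalysisDataset
from .design import ABIOTIC, BIOTIC, ScaleSpec, VariableSet, all_scales, build_design
from .nbglm import NbGlmFit, adjusted_d2, fit_nb_glm, format_adjusted_d2


@dataclass
class RichnessComparison:
    scale: ScaleSpec
    fits: dict[str, NbGlmFit]
    aic: dict[str, float]
    adj_d2: dict[str, float]
    winner: str  # variable set with the lower AIC

    def coefficient_table(self, vset_name: str) -> pd.DataFrame:
        return self.fits[vset_name].summary_frame()


def fit_scale_models(
    dataset: AnalysisDataset,
    scale: ScaleSpec,
    min_samples: int = 10,
    variable_sets: tuple[VariableSet, ...] = (ABIOTIC, BIOTIC),
) -> RichnessComparison:
    """Fit the richness model for each variable set within one scope."""
    mask = scale.select(dataset.samples)
    if mask.sum() < min_samples:
        raise ValueError(
            f"scope {scale.label()} has {mask.sum()} samples (< {min_samples})"
        )
    y = dataset.richness.to_numpy()[mask]
    fits, aic, d2 = {}, {}, {}
    for vset in variable_sets:
        X, offset = build_design(
            dataset.samples, dataset.library_size, vset, scale, mode="richness"
        )
        fit = fit_nb_glm(y, X, offset=offset)
        fits[vset.name] = fit
        aic[vset.name] = fit.aic
        d2[vset.name] = adjusted_d2(fit)
    winner = min(aic, key=aic.get)
    return RichnessComparison(scale=scale, fits=fits, aic=aic, adj_d2=d2, winner=winner)


def richness_table(
    dataset: AnalysisDataset,
    scales: list[ScaleSpec] | None = None,
    min_samples: int = 10,
) -> pd.DataFrame:
    """AIC / adjusted-D² comparison, one row per site, region and overall.

    Negative adjusted D² values are rendered as "0 (value)" in the
    formatted columns; raw values are kept alongside.
    """
    if scales is None:
        scales = all_scales(dataset)
    rows = []
    for scale in scales:
        cmp = fit_scale_models(dataset, scale, min_samples=min_samples)
        rows.append(
            {
                "scope": cmp.scale.label(),
                "level": cmp.scale.level,
                "aic_abiotic": cmp.aic["abiotic"],
                "adj_d2_abiotic": cmp.adj_d2["abiotic"],
                "aic_biotic": cmp.aic["biotic"],
                "adj_d2_biotic": cmp.adj_d2["biotic"],
                "winner": cmp.winner,
                "adj_d2_abiotic_fmt": format_adjusted_d2(cmp.adj_d2["abiotic"]),
                "adj_d2_biotic_fmt": format_adjusted_d2(cmp.adj_d2["biotic"]),
            }
        )
    return pd.DataFrame(rows)
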