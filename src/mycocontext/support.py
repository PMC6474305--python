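"""Per-OTU abundance models and ΔAIC support classification.

Each OTU's counts are modelled twice within a scope — once with the
abiotic design, once with the biotic design — as NB GLMs with
log(library size) as an offset (counts assumed proportional to
sequencing depth).  The OTU is classified as supporting whichever
variable set has the lower AIC when the gap exceeds a threshold
(default ΔAIC > 2; a gap of exactly 2 or less is "no support").  ΣAIC,
the total AIC over all analysed OTUs under one variable set, compares
the sets at the community level; it can disagree with the majority
label when a minority of OTUs carries very large AIC differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import AnalysisDataset
from .design import ABIOTIC, BIOTIC, ScaleSpec, build_design
from .nbglm import fit_nb_glm

logger = logging.getLogger(__name__)

LABELS = ("abiotic", "biotic", "no_support")


def filter_otus(
    counts: pd.DataFrame, min_prevalence: int = 5, min_total: int = 0
) -> pd.DataFrame:
    """Keep OTUs present in >= min_prevalence samples with total count >= min_total.

    Applied within the analysis scope, so regional filtering can retain
    OTUs that are absent from one member site.
    """
    if min_prevalence < 0 or min_total < 0:
        raise ValueError("thresholds must be non-negative")
    arr = counts.to_numpy()
    keep = ((arr > 0).sum(axis=0) >= min_prevalence) & (arr.sum(axis=0) >= min_total)
    if not keep.any():
        raise ValueError("no OTU passes the abundance filter")
    return counts.loc[:, counts.columns[keep]]


def classify_support(aic_abiotic: float, aic_biotic: float, threshold: float = 2.0) -> str:
    """Label by ΔAIC = aic_abiotic - aic_biotic; |Δ| must exceed the threshold."""
    delta = aic_abiotic - aic_biotic
    if not (math.isfinite(aic_abiotic) and math.isfinite(aic_biotic)):
        raise ValueError("AIC values must be finite")
    if delta > threshold:
        return "biotic"
    if delta < -threshold:
        return "abiotic"
    return "no_support"


@dataclass
class SupportSummary:
    scale: ScaleSpec
    n_otus_analysed: int
    proportions: dict[str, float]
    sigma_aic_abiotic: float
    sigma_aic_biotic: float
    sigma_aic_winner: str


def fit_per_otu_models(
    dataset: AnalysisDataset,
    scale: ScaleSpec,
    min_prevalence: int = 5,
    min_total: int = 0,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Fit the abiotic and biotic abundance model for every retained OTU.

    Returns one row per OTU: aic_abiotic, aic_biotic, delta
    (= aic_abiotic - aic_biotic) and the support label.  Fit failures
    are flagged "unfit" and excluded from summaries without aborting
    the scan.
    """
    mask = scale.select(dataset.samples)
    counts = filter_otus(dataset.counts.loc[mask], min_prevalence, min_total)
    designs = {}
    for vset in (ABIOTIC, BIOTIC):
        designs[vset.name] = build_design(
            dataset.samples, dataset.library_size, vset, scale, mode="abundance"
        )
    rows = []
    n_unfit = 0
    for otu in counts.columns:
        y = counts[otu].to_numpy()
        rec = {"otu_id": otu}
        try:
            for name, (X, offset) in designs.items():
                fit = fit_nb_glm(y, X, offset=offset)
                rec[f"aic_{name}"] = fit.aic
            rec["delta"] = rec["aic_abiotic"] - rec["aic_biotic"]
            rec["label"] = classify_support(rec["aic_abiotic"], rec["aic_biotic"], threshold)
        except Exception as exc:
            logger.warning("OTU %s unfit: %s", otu, exc)
            rec.update({"aic_abiotic": np.nan, "aic_biotic": np.nan,
                        "delta": np.nan, "label": "unfit"})
            n_unfit += 1
        rows.append(rec)
    if n_unfit:
        logger.info("support scan: %d of %d OTUs unfit", n_unfit, len(counts.columns))
    return pd.DataFrame(rows)


def support_summary(per_otu: pd.DataFrame, scale: ScaleSpec) -> SupportSummary:
    """Label proportions and ΣAIC per variable set over analysed OTUs."""
    ok = per_otu.loc[per_otu["label"] != "unfit"]
    if len(ok) == 0:
        raise ValueError("no successfully fitted OTU to summarise")
    n = len(ok)
    props = {lab: float((ok["label"] == lab).mean()) for lab in LABELS}
    sig_a = float(ok["aic_abiotic"].sum())
    sig_b = float(ok["aic_biotic"].sum())
    return SupportSummary(
        scale=scale,
        n_otus_analysed=n,
        proportions=props,
        sigma_aic_abiotic=sig_a,
        sigma_aic_biotic=sig_b,
        sigma_aic_winner="abiotic" if sig_a <= sig_b else "biotic",
    )


def summary_table(summaries: list[SupportSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "scope": s.scale.label(),
                "level": s.scale.level,
                "n_otus": s.n_otus_analysed,
                "prop_abiotic": s.proportions["abiotic"],
                "prop_biotic": s.proportions["biotic"],
                "prop_no_support": s.proportions["no_support"],
                "sigma_aic_abiotic": s.sigma_aic_abiotic,
                "sigma_aic_biotic": s.sigma_aic_biotic,
                "sigma_aic_winner": s.sigma_aic_winner,
            }
        )
    return pd.DataFrame(rows)
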