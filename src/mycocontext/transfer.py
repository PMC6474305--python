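"""Cross-site transferability of richness models.

A richness model is trained on each site and applied to every site's
covariates (including its own), giving a square matrix of predictive
errors (RMSE between predicted and observed richness).  Whether models
generalise better within than between regions is tested by a one-way
ANOVA on the log-transformed errors, with matrix cells grouped into
within-region transfers (one group per region, same-site cells
included) and between-region transfers, followed by Tukey HSD.

With six sites in two regions of three this yields groups of 9, 9 and
18 cells and an F statistic on (2, 33) degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import AnalysisDataset
from .design import ScaleSpec, VariableSet, build_design
from .nbglm import NbGlmFit, fit_nb_glm, predict_mean

logger = logging.getLogger(__name__)


@dataclass
class PredictiveErrorMatrix:
    """RMSE for every ordered (training site, target site) pair.

    ``values`` rows are training sites, columns target sites; diagonal
    entries are in-sample errors.
    """

    values: pd.DataFrame
    variable_set: str
    site_region: dict[str, str]


@dataclass
class TransferAnova:
    groups: pd.DataFrame  # train, target, group, rmse, log_rmse
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    tukey: pd.DataFrame  # pairwise group comparisons with adjusted P


def predictive_error(
    fit: NbGlmFit,
    target_design: pd.DataFrame,
    target_richness,
    target_offset=None,
) -> float:
    """Root-mean-square error between predicted and observed richness."""
    obs = np.asarray(target_richness, dtype=float)
    if obs.size == 0:
        raise ValueError("empty prediction target")
    pred = predict_mean(fit, target_design, target_offset)
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def transfer_matrix(dataset: AnalysisDataset, vset: VariableSet) -> PredictiveErrorMatrix:
    """Train on each site, predict richness at every site, record RMSE.

    Site-scale models contain no site factor, so cross-site prediction
    only requires the season levels (present at every site by design)
    and the continuous covariates.  A failed fit leaves its row missing
    with the cause logged.
    """
    sites = dataset.sites
    if len(sites) < 2:
        raise ValueError("transfer analysis needs at least two sites")
    values = pd.DataFrame(np.nan, index=sites, columns=sites, dtype=float)
    designs = {}
    for site in sites:
        scale = ScaleSpec("site", site)
        X, _ = build_design(
            dataset.samples, dataset.library_size, vset, scale, mode="richness"
        )
        mask = scale.select(dataset.samples)
        designs[site] = (X, dataset.richness.to_numpy()[mask])
    for train in sites:
        X_train, y_train = designs[train]
        try:
            fit = fit_nb_glm(y_train, X_train)
        except Exception as exc:  # leave the row missing, keep scanning
            logger.warning("transfer fit failed for site %s: %s", train, exc)
            continue
        for target in sites:
            X_t, y_t = designs[target]
            values.loc[train, target] = predictive_error(fit, X_t, y_t)
    return PredictiveErrorMatrix(
        values=values, variable_set=vset.name, site_region=dataset.site_region()
    )


def classify_cells(matrix: PredictiveErrorMatrix) -> pd.DataFrame:
    """Label each (train, target) cell within-region (per region) or between."""
    rows = []
    for train in matrix.values.index:
        for target in matrix.values.columns:
            r_train = matrix.site_region[train]
            r_target = matrix.site_region[target]
            group = f"within-{r_train}" if r_train == r_target else "between-region"
            rows.append(
                {
                    "train": train,
                    "target": target,
                    "group": group,
                    "rmse": matrix.values.loc[train, target],
                }
            )
    return pd.DataFrame(rows)


def region_transfer_anova(matrix: PredictiveErrorMatrix) -> TransferAnova:
    """One-way ANOVA (and Tukey HSD) on log predictive errors by group.

    Same-site (diagonal) cells are included in the within-region groups;
    zero errors are guarded by substituting half the smallest positive
    entry before the log.
    """
    cells = classify_cells(matrix).dropna(subset=["rmse"])
    vals = cells["rmse"].to_numpy(dtype=float)
    if (vals <= 0).any():
        floor = vals[vals > 0].min() / 2.0
        logger.warning("zero RMSE cell(s); flooring at %g before log", floor)
        vals = np.maximum(vals, floor)
    cells = cells.assign(log_rmse=np.log(vals))
    names = sorted(cells["group"].unique())
    if len(names) < 2:
        raise ValueError("need at least two transfer groups for ANOVA")
    samples = [cells.loc[cells["group"] == g, "log_rmse"].to_numpy() for g in names]
    f_stat, p = stats.f_oneway(*samples)
    df_between = len(names) - 1
    df_within = len(cells) - len(names)
    tk = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            ci = tk.confidence_interval()
            pairs.append(
                {
                    "group_1": names[i],
                    "group_2": names[j],
                    "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "ci_low": float(ci.low[i, j]),
                    "ci_high": float(ci.high[i, j]),
                    "p_adj": float(tk.pvalue[i, j]),
                }
            )
    return TransferAnova(
        groups=cells.reset_index(drop=True),
        f_statistic=float(f_stat),
        df=(df_between, df_within),
        p_value=float(p),
        tukey=pd.DataFrame(pairs),
    )
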