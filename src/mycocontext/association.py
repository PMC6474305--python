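"""Ecogroup x trophic-group association via permutation chi-squared.

Observed counts O cross-tabulate ecogroup assignment against FUNGuild
trophic group; expected counts under independence are
E_ij = row_i * col_j / N.  The statistic X^2 = sum (O-E)^2 / E is
referred to a permutation null built by shuffling the guild labels
across OTUs (default 10,000 permutations), with the add-one estimator
p = (1 + #{X^2_perm >= X^2_obs}) / (n_perm + 1), whose attainable floor
is 1/(n_perm+1).  This Monte-Carlo test doubles as the Fisher-style
exact test on the same statistic: both use the identical permutation
scheme, so a single P-value is reported.

OTUs without a guild assignment are excluded by default; most OTUs in
environmental surveys are unassigned, and the test concerns the
assigned trophic groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import UNASSIGNED

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi_squared: float
    p_perm: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def _crosstab(eco: pd.Series, guild: pd.Series) -> pd.DataFrame:
    tab = pd.crosstab(eco, guild)
    # X^2 is undefined with empty margins; drop such levels
    zero_rows = tab.index[tab.sum(axis=1) == 0].tolist()
    zero_cols = tab.columns[tab.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        logger.warning("dropping empty margin level(s): %s %s", zero_rows, zero_cols)
        tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    return tab


def contingency_expected(
    labels_ecogroup, labels_guild, include_unassigned: bool = False
) -> ContingencyResult:
    """Observed and independence-expected counts with X^2 (no P-value)."""
    eco = pd.Series(labels_ecogroup).reset_index(drop=True)
    guild = pd.Series(labels_guild).reset_index(drop=True)
    if len(eco) != len(guild):
        raise ValueError("label vectors differ in length")
    if not include_unassigned:
        keep = guild != UNASSIGNED
        eco, guild = eco[keep], guild[keep]
    if len(eco) == 0:
        raise ValueError("no OTUs left after excluding unassigned guilds")
    obs = _crosstab(eco, guild)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("association test needs >= 2 levels of each factor")
    O = obs.to_numpy(dtype=float)
    row, col = O.sum(axis=1), O.sum(axis=0)
    E = np.outer(row, col) / O.sum()
    chi2 = float(((O - E) ** 2 / E).sum())
    expected = pd.DataFrame(E, index=obs.index, columns=obs.columns)
    return ContingencyResult(observed=obs, expected=expected, chi_squared=chi2)


def permutation_chi_squared(
    labels_ecogroup,
    labels_guild,
    n_perm: int = 10_000,
    seed: int = 0,
    include_unassigned: bool = False,
    chunk: int = 2_000,
) -> ContingencyResult:
    """Permutation P-value for the ecogroup x guild X^2 statistic."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    base = contingency_expected(labels_ecogroup, labels_guild, include_unassigned)
    # rebuild the filtered label vectors to permute
    eco_s = pd.Series(labels_ecogroup).reset_index(drop=True)
    gld_s = pd.Series(labels_guild).reset_index(drop=True)
    if not include_unassigned:
        keep = gld_s != UNASSIGNED
        eco_s, gld_s = eco_s[keep].reset_index(drop=True), gld_s[keep].reset_index(drop=True)
    eco_codes = pd.Categorical(eco_s, categories=list(base.observed.index)).codes
    gld_codes = pd.Categorical(gld_s, categories=list(base.observed.columns)).codes
    valid = (eco_codes >= 0) & (gld_codes >= 0)  # levels dropped for empty margins
    eco_codes, gld_codes = eco_codes[valid], gld_codes[valid]
    G, F = base.observed.shape
    N = len(eco_codes)
    row = np.bincount(eco_codes, minlength=G).astype(float)
    col = np.bincount(gld_codes, minlength=F).astype(float)
    E = np.outer(row, col) / N
    rng = np.random.default_rng(seed)
    n_ge = 0
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b independent permutations of the guild labels
        idx = np.argsort(rng.random((b, N)), axis=1)
        perm_gld = gld_codes[idx]
        flat = (
            np.arange(b)[:, None] * (G * F) + eco_codes[None, :] * F + perm_gld
        )
        counts = np.bincount(flat.ravel(), minlength=b * G * F).reshape(b, G, F)
        chi2 = (((counts - E[None]) ** 2) / E[None]).sum(axis=(1, 2))
        n_ge += int(np.sum(chi2 >= base.chi_squared - 1e-9))
        done += b
    p = (1 + n_ge) / (n_perm + 1)
    return ContingencyResult(
        observed=base.observed,
        expected=base.expected,
        chi_squared=base.chi_squared,
        p_perm=float(p),
        n_perm=n_perm,
        seed=seed,
    )


def panel_table(result: ContingencyResult) -> pd.DataFrame:
    """Per-ecogroup observed/expected panel data (long format)."""
    rows = []
    for g in result.observed.index:
        for f in result.observed.columns:
            rows.append(
                {
                    "ecogroup": g,
                    "trophic_group": f,
                    "observed": int(result.observed.loc[g, f]),
                    "expected": float(result.expected.loc[g, f]),
                }
            )
    return pd.DataFrame(rows)
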