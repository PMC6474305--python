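"""Input tables, validation, alignment, richness and rarefaction.

The pipeline consumes three tab-separated tables:

``samples.tsv``
    One row per sediment core / quadrat sample: site, region, season and
    the measured abiotic (salinity, pH, soil moisture) and biotic
    (plant richness, root biomass, percentage cover of five plant
    groups) covariates.
``otus.tsv``
    Integer OTU count matrix, one row per sample, one column per OTU,
    first column ``sample_id``.  Library size is defined as the row sum.
``guilds.tsv`` (optional)
    FUNGuild-style mapping from OTU id to trophic group (pathotroph,
    saprotroph, symbiotroph, their pairwise combinations, or
    "unassigned").

All tables are UTF-8, tab-delimited, '.' decimal separator.  Cover
variables are percentages on the 0-100 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns required in the sample metadata table
SAMPLE_COLUMNS = [
    "sample_id",
    "site",
    "region",
    "season",
    "salinity",
    "ph",
    "moisture",
    "plant_richness",
    "root_biomass",
    "cover_herb",
    "cover_shrub",
    "cover_grass",
    "cover_sedge",
    "cover_rush",
]

COVER_COLUMNS = ["cover_herb", "cover_shrub", "cover_grass", "cover_sedge", "cover_rush"]

SEASONS = ("summer", "winter")

#: the six FUNGuild trophic groups plus the default fill label
TROPHIC_GROUPS = (
    "pathotroph",
    "saprotroph",
    "symbiotroph",
    "pathotroph-saprotroph",
    "pathotroph-symbiotroph",
    "saprotroph-symbiotroph",
)
UNASSIGNED = "unassigned"


class SchemaError(ValueError):
    """A required column is missing or a column has the wrong type."""


class AlignmentError(ValueError):
    """Sample or OTU identifiers do not line up across tables."""


class ValidationError(ValueError):
    """A table violates one of its invariants."""


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table is missing column(s): {', '.join(missing)}")
    samples = samples.loc[:, SAMPLE_COLUMNS].copy()
    if samples["sample_id"].duplicated().any():
        dups = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids: {dups}")
    if samples[SAMPLE_COLUMNS].isna().any().any():
        bad = samples.columns[samples.isna().any()].tolist()
        raise ValidationError(f"missing values in modelled column(s): {bad}")
    # each site must belong to exactly one region
    nreg = samples.groupby("site")["region"].nunique()
    if (nreg > 1).any():
        raise ValidationError(
            f"site(s) mapped to multiple regions: {nreg.index[nreg > 1].tolist()}"
        )
    bad_season = set(samples["season"]) - set(SEASONS)
    if bad_season:
        raise ValidationError(f"unknown season level(s): {sorted(bad_season)}")
    for c in COVER_COLUMNS:
        vals = samples[c].astype(float)
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError(f"{c} outside [0, 100]")
    if ((samples["ph"] < 0) | (samples["ph"] > 14)).any():
        raise ValidationError("ph outside [0, 14]")
    if (samples["salinity"] < 0).any() or (samples["root_biomass"] < 0).any():
        raise ValidationError("negative salinity or root biomass")
    return samples.reset_index(drop=True)


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check an OTU count matrix (index = sample ids, columns = OTU ids)."""
    if counts.columns.duplicated().any():
        raise ValidationError(
            f"duplicate otu ids: {counts.columns[counts.columns.duplicated()].tolist()}"
        )
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise SchemaError("OTU counts must be numeric")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        r, c = np.argwhere((arr < 0) | ~np.isclose(arr, np.round(arr)))[0]
        raise ValidationError(
            f"negative or non-integer count at sample {counts.index[r]!r}, "
            f"otu {counts.columns[c]!r}"
        )
    counts = counts.astype(np.int64)
    counts.index.name = "sample_id"
    lib = counts.sum(axis=1)
    if (lib == 0).any():
        raise ValidationError(
            f"zero library size for sample(s): {lib.index[lib == 0].tolist()}"
        )
    return counts


@dataclass
class AnalysisDataset:
    """Aligned sample metadata, OTU counts and guild labels.

    Attributes
    ----------
    samples : pd.DataFrame
        Validated metadata, one row per sample.
    counts : pd.DataFrame
        Integer counts, index aligned to ``samples["sample_id"]``.
    guilds : pd.Series
        otu_id -> trophic group; OTUs absent from the guild table are
        labelled ``"unassigned"``.
    richness : pd.Series
        Per-sample number of OTUs with count > 0, computed on the full
        unfiltered table.
    """

    samples: pd.DataFrame
    counts: pd.DataFrame
    guilds: pd.Series = field(default=None)
    richness: pd.Series = field(default=None)

    def __post_init__(self):
        self.samples = validate_samples(self.samples)
        self.counts = validate_counts(self.counts)
        sids = self.samples["sample_id"]
        extra = set(self.counts.index) - set(sids)
        missing = set(sids) - set(self.counts.index)
        if extra or missing:
            raise AlignmentError(
                "sample ids differ between metadata and OTU table: "
                f"only in OTU table {sorted(extra)}, only in metadata {sorted(missing)}"
            )
        self.counts = self.counts.loc[sids.to_numpy()]
        if self.guilds is None:
            self.guilds = pd.Series(UNASSIGNED, index=self.counts.columns, name="trophic_group")
        else:
            if self.guilds.index.duplicated().any():
                raise ValidationError("duplicate otu ids in guild table")
            allowed = set(TROPHIC_GROUPS) | {UNASSIGNED}
            bad = set(self.guilds) - allowed
            if bad:
                raise ValidationError(f"unknown trophic group label(s): {sorted(bad)}")
            self.guilds = self.guilds.reindex(self.counts.columns).fillna(UNASSIGNED)
            self.guilds.name = "trophic_group"
        self.richness = compute_richness(self.counts)

    @property
    def library_size(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def sites(self) -> list[str]:
        return sorted(self.samples["site"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.samples["region"].unique())

    def site_region(self) -> dict[str, str]:
        return dict(self.samples.groupby("site")["region"].first())


def compute_richness(counts: pd.DataFrame) -> pd.Series:
    """Number of OTUs observed (count > 0) in each sample."""
    r = (counts.to_numpy() > 0).sum(axis=1)
    return pd.Series(r, index=counts.index, name="richness")


def rarefy(counts: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample each sample's reads without replacement to a common depth.

    Samples with fewer than ``depth`` reads are dropped (with a logged
    warning), mirroring the exclusion of under-sequenced samples rather
    than up-sampling them.  A single seeded draw is taken per sample.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    lib = counts.sum(axis=1)
    keep = lib >= depth
    if not keep.any():
        raise ValidationError(f"no sample reaches rarefaction depth {depth}")
    if (~keep).any():
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            (~keep).sum(), depth, lib.index[~keep].tolist(),
        )
    rng = np.random.default_rng(seed)
    kept = counts.loc[keep]
    out = np.empty(kept.shape, dtype=np.int64)
    for i, row in enumerate(kept.to_numpy()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    return pd.DataFrame(out, index=kept.index, columns=kept.columns)


def read_dataset(
    samples_path: str | Path,
    otus_path: str | Path,
    guilds_path: str | Path | None = None,
) -> AnalysisDataset:
    """Read, validate and align the three input tables.

    OTUs absent from the guild table (or all OTUs, when no guild file is
    given) are labelled "unassigned"; stages that do not need guild
    information run regardless.
    """
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str})
    otus = pd.read_csv(otus_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in otus.columns:
        raise SchemaError("OTU table is missing column(s): sample_id")
    otus = otus.set_index("sample_id")
    guilds = None
    if guilds_path is not None:
        g = pd.read_csv(guilds_path, sep="\t", dtype=str)
        for c in ("otu_id", "trophic_group"):
            if c not in g.columns:
                raise SchemaError(f"guild table is missing column(s): {c}")
        guilds = g.set_index("otu_id")["trophic_group"]
    ds = AnalysisDataset(samples=samples, counts=otus, guilds=guilds)
    logger.info(
        "read_dataset: %d samples, %d OTUs, guild coverage %.1f%%",
        len(ds.samples), ds.counts.shape[1],
        100.0 * (ds.guilds != UNASSIGNED).mean(),
    )
    return ds


def write_dataset(ds: AnalysisDataset, outdir: str | Path) -> dict[str, Path]:
    """Write samples.tsv, otus.tsv and guilds.tsv; inverse of read_dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": outdir / "samples.tsv",
        "otus": outdir / "otus.tsv",
        "guilds": outdir / "guilds.tsv",
    }
    ds.samples.to_csv(paths["samples"], sep="\t", index=False)
    ds.counts.rename_axis("sample_id").reset_index().to_csv(
        paths["otus"], sep="\t", index=False
    )
    ds.guilds.rename_axis("otu_id").reset_index().to_csv(
        paths["guilds"], sep="\t", index=False
    )
    return paths
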