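"""End-to-end orchestration with seeded, reproducible stages.

Stage order: read or simulate the dataset; richness models at the
requested scales; cross-site transfer matrix and region ANOVA (both
variable sets); per-OTU support classification; rarefaction; ecogroup
mixtures for the abiotic and the biotic covariates independently; and
the guild association test for each.  Every stage writes TSV output
and the run ends with a JSON manifest (seeds, config hash, per-stage
wall time).  Identical config and seeds give byte-identical numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import panel_table, permutation_chi_squared
from .datasets import AnalysisDataset, rarefy, read_dataset, write_dataset
from .design import ABIOTIC, BIOTIC, ScaleSpec, all_scales
from .ecogroups import (
    assign_ecogroups,
    coefficient_profiles,
    fit_archetype_mixture,
    mixture_design,
)
from .richness import richness_table
from .simulate import SimulationConfig, simulate_dataset
from .support import fit_per_otu_models, summary_table, support_summary
from .transfer import region_transfer_anova, transfer_matrix

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"  # fixed formatting => byte-identical reruns


@dataclass
class PipelineConfig:
    """Defaults follow the reference workflow: rarefaction to 12,738
    sequences per sample, 6 ecogroups, ΔAIC threshold 2, 10,000
    permutations."""

    samples_path: str | None = None
    otus_path: str | None = None
    guilds_path: str | None = None
    simulation: SimulationConfig | None = None
    scales: tuple[str, ...] = ("site", "region", "overall")
    rarefaction_depth: int = 12_738
    G: int = 6
    delta_aic_threshold: float = 2.0
    n_perm: int = 10_000
    min_prevalence: int = 5
    min_total: int = 0
    min_samples_per_scope: int = 10
    mixture_starts: int = 3
    mixture_max_iter: int = 500
    support_levels: tuple[str, ...] = ("site", "region", "overall")
    seed: int = 0

    def seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ["simulate", "rarefy", "mixture_abiotic", "mixture_biotic",
                 "association_abiotic", "association_biotic"]
        children = ss.spawn(len(names))
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in dataclasses.asdict(self.simulation).items()
            }
        return d


def _write(df: pd.DataFrame, path: Path, index: bool = False):
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _selected_scales(dataset: AnalysisDataset, levels) -> list[ScaleSpec]:
    return [s for s in all_scales(dataset) if s.level in levels]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.seeds()
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(status="ok", **extra):
            manifest["stages"][name] = {
                "status": status,
                "seconds": round(time.perf_counter() - t0, 3),
                **extra,
            }

        return done

    try:
        # --- input ---------------------------------------------------
        done = stage("input")
        if config.simulation is not None:
            sim = dataclasses.replace(config.simulation, seed=seeds["simulate"])
            dataset, truth = simulate_dataset(sim)
            write_dataset(dataset, outdir)
            (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))
        elif config.samples_path and config.otus_path:
            dataset = read_dataset(config.samples_path, config.otus_path, config.guilds_path)
        else:
            raise ValueError("config needs either input paths or a simulation block")
        done(n_samples=len(dataset.samples), n_otus=dataset.counts.shape[1])

        # --- richness scaling ---------------------------------------
        done = stage("richness")
        rtab = richness_table(
            dataset,
            _selected_scales(dataset, config.scales),
            min_samples=config.min_samples_per_scope,
        )
        _write(rtab, outdir / "richness_comparison.tsv")
        done()

        # --- transfer ------------------------------------------------
        done = stage("transfer")
        anova_rows = []
        for vset in (ABIOTIC, BIOTIC):
            mat = transfer_matrix(dataset, vset)
            _write(mat.values.rename_axis("train"), outdir / f"transfer_rmse_{vset.name}.tsv",
                   index=True)
            an = region_transfer_anova(mat)
            anova_rows.append(
                {
                    "variable_set": vset.name,
                    "F": an.f_statistic,
                    "df_between": an.df[0],
                    "df_within": an.df[1],
                    "p": an.p_value,
                }
            )
            _write(an.tukey, outdir / f"transfer_tukey_{vset.name}.tsv")
        _write(pd.DataFrame(anova_rows), outdir / "transfer_anova.tsv")
        done()

        # --- per-OTU support ----------------------------------------
        done = stage("support")
        summaries = []
        for scale in _selected_scales(dataset, config.support_levels):
            per_otu = fit_per_otu_models(
                dataset,
                scale,
                min_prevalence=config.min_prevalence,
                min_total=config.min_total,
                threshold=config.delta_aic_threshold,
            )
            _write(per_otu, outdir / f"support_{scale.level}_{scale.label()}.tsv")
            summaries.append(support_summary(per_otu, scale))
        _write(summary_table(summaries), outdir / "support_summary.tsv")
        done()

        # --- rarefaction --------------------------------------------
        done = stage("rarefy")
        rare = rarefy(dataset.counts, config.rarefaction_depth, seeds["rarefy"])
        done(n_samples_retained=len(rare))

        # --- ecogroups + association --------------------------------
        rare_samples = dataset.samples.loc[
            dataset.samples["sample_id"].isin(rare.index)
        ].reset_index(drop=True)
        from .support import filter_otus

        rare_f = filter_otus(rare, config.min_prevalence, config.min_total)
        for vset in (ABIOTIC, BIOTIC):
            done = stage(f"ecogroups_{vset.name}")
            X = mixture_design(rare_samples, vset)
            model = fit_archetype_mixture(
                rare_f,
                X,
                G=config.G,
                n_starts=config.mixture_starts,
                seed=seeds[f"mixture_{vset.name}"],
                max_iter=config.mixture_max_iter,
            )
            assign = assign_ecogroups(model)
            _write(coefficient_profiles(model), outdir / f"ecogroup_profiles_{vset.name}.tsv")
            _write(assign.table, outdir / f"ecogroup_assignments_{vset.name}.tsv")
            tau = pd.DataFrame(
                model.tau,
                index=pd.Index(model.otu_ids, name="otu_id"),
                columns=[f"ecogroup_{g + 1}" for g in range(model.G)],
            )
            _write(tau, outdir / f"ecogroup_tau_{vset.name}.tsv", index=True)
            (outdir / f"ecogroup_model_{vset.name}.json").write_text(
                json.dumps(
                    {
                        "G": model.G,
                        "pi": model.pi.tolist(),
                        "beta": model.beta.tolist(),
                        "theta": model.theta.tolist(),
                        "log_likelihood": model.log_likelihood,
                        "converged": model.converged,
                        "n_starts": model.n_starts,
                        "seed": model.seed,
                        "terms": model.term_names,
                    },
                    indent=1,
                )
            )
            done(log_likelihood=model.log_likelihood, converged=model.converged)

            done = stage(f"association_{vset.name}")
            if config.G < 2:
                logger.info("G=%d: association test skipped (needs >= 2 ecogroups)",
                            config.G)
                done(status="skipped", reason="G < 2")
                continue
            guilds = dataset.guilds.loc[assign.table["otu_id"]]
            try:
                res = permutation_chi_squared(
                    assign.table["ecogroup"].to_numpy(),
                    guilds.to_numpy(),
                    n_perm=config.n_perm,
                    seed=seeds[f"association_{vset.name}"],
                )
            except ValueError as exc:
                logger.warning("association test skipped (%s): %s", vset.name, exc)
                done(status="skipped", reason=str(exc))
                continue
            _write(panel_table(res), outdir / f"association_panels_{vset.name}.tsv")
            _write(
                pd.DataFrame(
                    [
                        {
                            "variable_set": vset.name,
                            "chi_squared": res.chi_squared,
                            "p_perm": res.p_perm,
                            "n_perm": res.n_perm,
                            "seed": res.seed,
                        }
                    ]
                ),
                outdir / f"association_test_{vset.name}.tsv",
            )
            done(chi_squared=res.chi_squared, p_perm=res.p_perm)

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
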