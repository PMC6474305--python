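"""OTU filtering, ΔAIC classification and community-level summaries."""

import numpy as np
import pandas as pd
import pytest

import mycocontext as mc
from mycocontext.design import ScaleSpec
from mycocontext.support import summary_table


class TestFilterOtus:
    def test_prevalence_rule(self):
        counts = pd.DataFrame([[1, 0], [1, 0], [0, 1]], columns=["o1", "o2"])
        out = mc.filter_otus(counts, min_prevalence=2)
        assert list(out.columns) == ["o1"]

    def test_zero_thresholds_are_identity(self):
        counts = pd.DataFrame([[1, 0], [0, 2]], columns=["o1", "o2"])
        out = mc.filter_otus(counts, min_prevalence=0, min_total=0)
        assert out.equals(counts)

    def test_scoped_filtering_can_keep_site_absent_otus(self):
        # o2 is absent from site 1 but prevalent regionally: regional
        # filtering keeps it, site-1 filtering drops it
        counts = pd.DataFrame(
            {"o1": [3, 2, 1, 4], "o2": [0, 0, 5, 6]},
            index=["s1a", "s1b", "s2a", "s2b"],
        )
        site1 = counts.loc[["s1a", "s1b"]]
        assert "o2" in mc.filter_otus(counts, min_prevalence=2).columns
        assert "o2" not in mc.filter_otus(site1, min_prevalence=1).columns

    def test_everything_removed_errors(self):
        counts = pd.DataFrame([[1, 1]], columns=["o1", "o2"])
        with pytest.raises(ValueError):
            mc.filter_otus(counts, min_prevalence=5)


@pytest.mark.parametrize(
    "aic_a, aic_b, expected",
    [
        (100.0, 103.0, "abiotic"),
        (103.0, 100.0, "biotic"),
        (100.0, 101.5, "no_support"),
        (100.0, 102.0, "no_support"),  # exactly 2 is not support
        (102.0, 100.0, "no_support"),
    ],
)
def test_classify_support_rules(aic_a, aic_b, expected):
    assert mc.classify_support(aic_a, aic_b) == expected


def test_classify_support_rejects_nonfinite():
    with pytest.raises(ValueError):
        mc.classify_support(np.nan, 1.0)


class TestSummary:
    def _frame(self, n_abiotic, n_biotic, n_none):
        labels = (
            ["abiotic"] * n_abiotic + ["biotic"] * n_biotic + ["no_support"] * n_none
        )
        n = len(labels)
        return pd.DataFrame(
            {
                "otu_id": [f"o{i}" for i in range(n)],
                "aic_abiotic": np.linspace(100, 200, n),
                "aic_biotic": np.linspace(110, 190, n),
                "label": labels,
            }
        )

    def test_reported_count_arithmetic(self):
        per = self._frame(1164, 588, 247)
        s = mc.support_summary(per, ScaleSpec("overall"))
        assert s.n_otus_analysed == 1999
        assert s.proportions["abiotic"] == pytest.approx(0.582, abs=5e-4)
        assert s.proportions["biotic"] == pytest.approx(0.294, abs=5e-4)
        assert s.proportions["no_support"] == pytest.approx(0.124, abs=5e-4)
        assert sum(s.proportions.values()) == pytest.approx(1.0)

    def test_single_otu(self):
        s = mc.support_summary(self._frame(1, 0, 0), ScaleSpec("overall"))
        assert s.proportions == {"abiotic": 1.0, "biotic": 0.0, "no_support": 0.0}

    def test_sigma_aic_is_plain_summation(self):
        per = self._frame(3, 2, 1)
        s = mc.support_summary(per, ScaleSpec("overall"))
        assert s.sigma_aic_abiotic == pytest.approx(per["aic_abiotic"].sum())
        assert s.sigma_aic_biotic == pytest.approx(per["aic_biotic"].sum())

    def test_majority_and_sigma_aic_can_disagree(self):
        """A minority of OTUs with huge AIC gaps can hand the community-level
        ΣAIC win to the other set than the per-OTU majority."""
        per = pd.DataFrame(
            {
                "otu_id": ["o1", "o2", "o3", "o4"],
                # three OTUs weakly favour biotic (delta = +3 each)...
                "aic_abiotic": [103.0, 103.0, 103.0, 100.0],
                "aic_biotic": [100.0, 100.0, 100.0, 400.0],
            }
        )
        per["label"] = [
            mc.classify_support(a, b)
            for a, b in zip(per["aic_abiotic"], per["aic_biotic"])
        ]
        s = mc.support_summary(per, ScaleSpec("overall"))
        assert s.proportions["biotic"] > s.proportions["abiotic"]
        assert s.sigma_aic_winner == "abiotic"  # ...one strongly favours abiotic


class TestPerOtuModels:
    @staticmethod
    def _single_site_cfg(beta, g, seed, n_otus=60):
        return mc.SimulationConfig(
            n_regions=1, sites_per_region=1, quadrats_per_site_season=22,
            region_names=("r",), n_otus=n_otus, G_true=g,
            beta_true=beta, pi_true=np.ones(g) / g, theta_true=np.ones(g),
            salinity={"region_mean": (25.0,), "region_sd": (6.0,), "site_shift": (0.0,)},
            ph={"region_mean": (6.8,), "region_sd": (0.35,), "site_shift": (0.0,)},
            moisture={"region_mean": (55.0,), "region_sd": (9.0,), "site_shift": (0.0,)},
            cover_weights=((2.0, 1.0, 3.0, 1.0, 1.0),),
            seed=seed,
        )

    def test_salinity_responders_classified_abiotic(self):
        # opposite-sign responses: relative abundances shift with salinity
        # (a shared response would be absorbed by the library-size offset)
        beta = np.zeros((2, 8))
        beta[0, 1], beta[1, 1] = 1.2, -1.2
        ds, _ = mc.simulate_dataset(self._single_site_cfg(beta, 2, seed=81))
        per = mc.fit_per_otu_models(ds, ScaleSpec("overall"), min_prevalence=5)
        ok = per[per["label"] != "unfit"]
        assert (ok["label"] == "abiotic").mean() >= 0.8

    def test_pure_offset_noise_centres_delta_at_parameter_gap(self):
        """With no planted effects, delta = AIC_abiotic - AIC_biotic centres
        near -3 (the biotic set has three more parameters, and expected
        overfitting 2*dLL ~ chi2_3 = 3 falls short of the 2*3 penalty), so
        biotic support should be rare and large gaps absent."""
        beta = np.zeros((1, 8))
        ds, _ = mc.simulate_dataset(self._single_site_cfg(beta, 1, seed=82))
        per = mc.fit_per_otu_models(ds, ScaleSpec("overall"), min_prevalence=5)
        ok = per[per["label"] != "unfit"]
        assert -6.0 < ok["delta"].median() < 0.0
        assert (ok["label"] == "biotic").mean() < 0.35
        assert (ok["delta"].abs() > 25).mean() < 0.1

    def test_per_otu_results_independent_of_other_columns(self, small_sim):
        ds, _ = small_sim
        scale = ScaleSpec("site", ds.sites[0])
        full = mc.fit_per_otu_models(ds, scale, min_prevalence=3)
        target = full["otu_id"].iloc[0]
        # rebuild the dataset with only a handful of OTU columns
        keep = full["otu_id"].iloc[:5].tolist()
        ds_small = mc.AnalysisDataset(
            samples=ds.samples.copy(), counts=ds.counts[keep].copy(),
            guilds=ds.guilds[keep].copy(),
        )
        # abundance models use per-sample library size from the full table;
        # hold it fixed by passing the original offsets through the design
        row_full = full.set_index("otu_id").loc[target]
        from mycocontext.design import ABIOTIC, BIOTIC, build_design

        y = ds.counts.loc[scale.select(ds.samples), target].to_numpy()
        rec = {}
        for vset in (ABIOTIC, BIOTIC):
            X, off = build_design(ds.samples, ds.library_size, vset, scale, "abundance")
            rec[vset.name] = mc.fit_nb_glm(y, X, offset=off).aic
        assert rec["abiotic"] == pytest.approx(row_full["aic_abiotic"], rel=1e-10)
        assert rec["biotic"] == pytest.approx(row_full["aic_biotic"], rel=1e-10)


def test_summary_table_shape(small_sim):
    ds, _ = small_sim
    scales = [ScaleSpec("site", ds.sites[0]), ScaleSpec("overall")]
    summaries = []
    for sc in scales:
        per = mc.fit_per_otu_models(ds, sc, min_prevalence=10)
        summaries.append(mc.support_summary(per, sc))
    tab = summary_table(summaries)
    assert list(tab["scope"]) == [ds.sites[0], "overall"]
    assert (tab[["prop_abiotic", "prop_biotic", "prop_no_support"]].sum(axis=1)
            .round(9) == 1.0).all()
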