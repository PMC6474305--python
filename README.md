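# mycocontext

Are the environmental drivers of root-associated fungal communities the
same everywhere, or do they depend on where — and at what scale — you
look?  `mycocontext` is a statistical pipeline for answering that
question with metabarcoding data from spatially nested surveys: several
sites in several regions, sampled across seasons, with an OTU count
table, per-sample environmental measurements and FUNGuild-style trophic
annotations.

It is aimed at microbial ecologists who want to compare **abiotic**
(site, season, salinity, pH, soil moisture) against **biotic** (plant
richness, root biomass, plant-group cover) explanations of fungal
richness and composition, and to test how well models trained in one
place transfer to another.

## What it computes

**Richness models at nested scales.**  OTU richness per sample is
modelled with negative-binomial GLMs (log link, NB2 variance
μ + μ²/θ, dispersion θ estimated by profile maximum likelihood),
with log(library size) as the first covariate.  Models are fitted per
site, per region (sites pooled, plus a site factor) and overall, once
with each variable set, and compared by AIC and adjusted
D² = 1 − ((n−1)/(n−p))(1 − D²), D² = 1 − deviance/null deviance.

**Cross-site transfer.**  Each site-trained richness model predicts
every site's richness; the RMSE between predicted and observed values
fills a training-site × target-site matrix.  A one-way ANOVA on log
errors (groups: within each region, between regions; Tukey HSD
post-hoc) asks whether models generalise better within regions.  With
6 sites in 2 regions the groups hold 9/9/18 cells and the F statistic
has (2, 33) degrees of freedom.

**Per-OTU support classification.**  Every OTU's counts are modelled
twice (abiotic/biotic designs, log-library offset with coefficient
fixed at 1); the OTU supports whichever set wins by ΔAIC > 2, else
"no support".  Label proportions and ΣAIC (total AIC over OTUs per
variable set) summarise each scope — the two can disagree when a
minority of OTUs carries very large AIC gaps.

**Ecogroups.**  OTUs are clustered by *response shape*, not abundance,
with a finite mixture of NB regressions (the species-archetype model):
component g has a shared coefficient vector β_g and dispersion θ_g,
each OTU keeps its own intercept αᵢ, and EM maximises

    ℓ(Θ) = Σᵢ log Σ_g π_g Π_j NB(y_ij; exp(αᵢ + x_jᵀβ_g), θ_g)

on a table rarefied to a common depth (default 12,738 reads).  The
default number of groups equals the six fungal trophic groups.

**Guild association.**  Ecogroup assignment × trophic group is
cross-tabulated; X² = Σ(O−E)²/E is referred to a permutation null
(guild labels shuffled across OTUs, default 10,000 permutations,
add-one P-value).

**Synthetic data.**  A generator emulates the target study design —
2 regions × 3 sites × 2 seasons × 22 quadrats (264 samples),
region-structured covariates, log-normal library sizes, NB counts with
archetype-shared responses and guild labels coupled to the archetypes —
and returns the generative truth, so every stage can be validated
end-to-end without any sequencing data.

## Worked example

```python
import mycocontext as mc

cfg = mc.SimulationConfig(n_otus=120, seed=11)
ds, truth = mc.simulate_dataset(cfg)

tab = mc.richness_table(ds)
print(tab[["scope", "aic_abiotic", "adj_d2_abiotic_fmt",
           "aic_biotic", "adj_d2_biotic_fmt", "winner"]].to_string(index=False))

an = mc.region_transfer_anova(mc.transfer_matrix(ds, mc.ABIOTIC))
print(f"abiotic transfer ANOVA: F({an.df[0]},{an.df[1]}) = "
      f"{an.f_statistic:.2f}, P = {an.p_value:.4f}")
```

prints

```
         scope  aic_abiotic adj_d2_abiotic_fmt  aic_biotic adj_d2_biotic_fmt  winner
region_a_site1        307.6               0.09       307.8              0.40 abiotic
region_a_site2        303.3               0.12       306.7              0.28 abiotic
region_a_site3        303.4               0.41       308.3              0.42 abiotic
region_b_site1        299.2               0.63       305.6              0.57 abiotic
region_b_site2        302.3               0.33       305.7              0.48 abiotic
region_b_site3        301.4               0.52       304.7              0.65 abiotic
      region_a        892.1               0.27       887.9              0.38  biotic
      region_b        880.4               0.52       880.4              0.55 abiotic
       overall       1762.5               0.39      1750.6              0.47  biotic

abiotic transfer ANOVA: F(2,33) = 19.74, P = 0.0000
```

Reading this: at the site scale the leaner abiotic model wins every
comparison (lower AIC), while pooling data across floristically
distinct regions hands the win to the biotic set — the scale-dependence
the pipeline is built to expose.  The transfer ANOVA rejects
equality of within- and between-region predictive errors, i.e. models
trained in one region extrapolate poorly to the other.  A negative
adjusted D² would be rendered `0 (-0.14)` in the formatted columns.

The same analyses are available from the shell:

```sh
mycocontext simulate --seed 11 --out data/
mycocontext richness --samples data/samples.tsv --otus data/otus.tsv --out out/
mycocontext all --seed 11 --out out/        # every stage + manifest.json
```

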