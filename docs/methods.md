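# Methods

This note documents the models behind `mycocontext`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the limitations a user should know about.  It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Negative-binomial GLMs

All count responses (per-sample OTU richness; per-OTU abundances) are
modelled as NB2: y ~ NB(μ, θ) with Var(y) = μ + μ²/θ and
log μ = Xβ (+ offset).  Coefficients are estimated by IRLS
(statsmodels' NegativeBinomial family with α = 1/θ), alternating with
one-dimensional profile maximisation of the exact log-likelihood over
log θ (bounded Brent search on θ ∈ [1e−4, 1e8]).  This alternation
reproduces the classical `glm.nb` estimator.  Convergence is declared
when the relative change in log-likelihood falls below 1e−8 (or after
200 outer iterations; the fit is then returned flagged
`converged=False`).  A secondary stop on a stable dispersion
(|Δlog θ| < 1e−7) guards against dithering when the likelihood is
maximised at the Poisson boundary (underdispersed data, θ → ∞).

Conventions:

* **AIC** = −2ℓ + 2p with p = number of regression coefficients + 1
  for the estimated dispersion.  The identity holds exactly by
  construction.  When θ is user-fixed it is not counted.
* **Null deviance** comes from an intercept-only model with the same
  offset and the same θ (the `glm.nb` convention).  Whether the null
  should instead include log(library size) as a covariate is
  genuinely open; intercept-only is the default, and richness models
  simply include log(library size) as an ordinary covariate so the
  question only affects D², not AIC comparisons.
* **Adjusted D²** = 1 − ((n−1)/(n−p))(1 − D²) with
  D² = 1 − deviance/null deviance.  It can be negative; reporting
  renders negatives as `0 (value)`.
* **Categoricals** use treatment contrasts with the lexicographically
  first level as reference.  `season` therefore enters as a winter
  dummy: positive coefficients mean higher in winter.
* **Wald z-tests** provide per-coefficient P-values (computed at the
  final θ), the default in the NB-GLM ecosystem.

## Variable sets, scales and library size

Abiotic terms: season, salinity, pH, soil moisture, plus a site factor
when data are pooled at regional or overall scale.  Biotic terms:
plant species richness, total root biomass, and percentage cover
(0–100) of herbs/forbs, shrubs, grasses, sedges and rushes.  Biotic
models never receive the site factor.  Terms constant within a scope
are dropped with a warning rather than producing singular designs.

Richness models include log(library size) as the first covariate after
the intercept; abundance models move it to an offset with coefficient
fixed at 1, i.e. counts are treated as proportional to sequencing
depth and the models describe relative abundance.  Library size is
defined as the OTU-table row sum.

## Cross-site transfer

For every ordered (train, target) site pair the site-trained richness
model predicts the target's richness from its covariates and library
sizes; the cell value is RMSE(predicted, observed).  Site-scale models
contain no site factor, so no level remapping is needed; both seasons
are present at every site by design.  Cells are grouped as
within-region (one group per region, **in-sample diagonal cells
included**) or between-region, and a one-way ANOVA with Tukey HSD is
run on log RMSE.  Diagonal inclusion is forced by the degrees-of-
freedom arithmetic of the 6-site/2-region design (groups 9/9/18,
F on (2, 33)); it is also a known source of anticonservatism — see
Limitations.

## ΔAIC support classification

Per OTU, Δ = AIC_abiotic − AIC_biotic; the label is `biotic` if Δ > 2,
`abiotic` if Δ < −2, else `no_support` (a gap of exactly 2 is not
support).  OTUs enter a scope's scan if present in ≥ 5 samples of that
scope (`min_prevalence`, configurable; the filter that produced the
original analyses' OTU subset is not documented, so this default is a
package choice).  Fit failures are flagged `unfit`, logged, and
excluded from summaries without aborting the scan.

Because the biotic design has three more parameters than the abiotic
design, Δ is not centred at zero under a no-effect null: expected
overfitting gain 2Δℓ ≈ χ²₍₃₎ (mean 3) falls short of the 2·3 = 6
penalty, so Δ centres near −3 and "abiotic" is the modal label for
pure-noise OTUs.  ΔAIC comparisons between variable sets of unequal
size carry this asymmetry inherently; interpret site-level support
proportions with it in mind.

ΣAIC (the per-set total over analysed OTUs) compares the sets at the
community level and can disagree with the majority label when a
minority of OTUs has very large gaps — both summaries are reported.

## Ecogroup mixture (species-archetype model)

The mixture likelihood is

ℓ(Θ) = Σᵢ log Σ_g π_g Π_j NB(y_ij; exp(αᵢ + x_jᵀβ_g), θ_g)

over OTUs i and samples j.  Choices, and the reasons:

* **Per-OTU intercepts αᵢ** (default) separate abundance level from
  response shape, so common and rare OTUs with the same environmental
  response cluster together.  Archetype formulations differ on this
  point; fitting proceeds identically with a shared intercept if the
  design carries one instead.
* **Per-group dispersion θ_g**, not per-OTU: keeps the M-step
  well-posed with many rare OTUs.
* **Input is a rarefied table** (single seeded draw to a common depth,
  default 12,738 reads; shallower samples are dropped, mirroring the
  exclusion of under-sequenced samples).  Equal row sums make an
  offset unnecessary; an offset argument exists for unrarefied use.
* **EM in log space.**  The E-step computes responsibilities τ with
  log-sum-exp.  The M-step updates π by τ-means; each (β_g, θ_g) by a
  τ-weighted NB regression (statsmodels `var_weights`) followed by
  weighted profile ML for θ_g; then αᵢ by vectorised Newton steps with
  per-OTU step-halving and rejection of non-improving steps.  Each
  partial update cannot decrease its own objective, so the
  observed-data log-likelihood is non-decreasing (generalised EM); the
  full trace is recorded on the fitted model.
* **Starts.**  Start 1 is deterministic: k-means on per-OTU
  independent NB-GLM slope vectors.  Remaining starts draw random
  responsibilities.  Best final likelihood wins; groups are reported
  in descending-π order (mixture labels are only identified up to
  permutation).
* **Stopping**: relative ℓ change < 1e−6 or 500 iterations.
* **Design**: covariates only, no intercept column; continuous terms
  are z-scored (`mixture_design`) so coefficient profiles are
  comparable across terms.  G defaults to 6, the number of fungal
  trophic groups, enabling a maximal one-to-one association scenario.
  Abiotic and biotic mixtures are fitted independently; their group
  numberings are unrelated.

OTUs are hard-assigned to their highest-membership group (ties break
toward the lowest index, logged).

## Guild association

Observed ecogroup × trophic-group counts O are compared with
independence expectations E_ij = rowᵢ·colⱼ/N via X² = Σ(O−E)²/E.
Significance comes from shuffling guild labels across OTUs (default
10,000 permutations) with the add-one estimator
p = (1 + #{X²_perm ≥ X²_obs})/(n_perm + 1), so p ∈ (0, 1] with floor
1/(n_perm+1).  Unassigned OTUs are excluded by default (most
environmental OTUs lack a guild; the test concerns the six assigned
groups); a switch includes them as a seventh category.  This
Monte-Carlo test is simultaneously the Fisher-style exact test on the
same statistic — one P-value is reported.  Levels with empty margins
are dropped with a warning (X² is undefined otherwise).

## Synthetic data

The generator mirrors the design the pipeline targets: 2 regions ×
3 sites × 2 seasons × 22 quadrats = 264 samples.  Defaults:

* **Salinity** N(32, 6²) in region A vs N(16, 3²) in region B (one
  region saltier *and* more variable), ±3 site shifts for tidal
  exposure; pH ≈ N(6.8, 0.35²); moisture ≈ N(55, 9²).
* **Plant community**: per-quadrat cover totals N(80, 12²) (clipped to
  [20, 100]) split by region-specific Dirichlet weights —
  shrub-dominated in region A, grass/sedge-dominated in region B.
  Totals vary per quadrat so the five covers are not compositionally
  closed (closure would make them collinear with the intercept).
  Plant richness Poisson(6); root biomass log-normal(1, 0.5).
* **Counts**: library sizes log-normal (median 20,000, log-sd 0.45);
  OTU i in true group g gets y_ij ~ NB(L_j·exp(αᵢ + x_jᵀβ_g), θ_g)
  with z-scored covariates x.  αᵢ ~ N(0, 2.5²), softmax-normalised so
  Σ exp(α) = 1 (row sums ≈ L).  The heavy α tail produces many rare
  OTUs, so richness responds to the environment purely through NB
  occupancy — nothing is injected into richness directly, matching the
  mechanism the fitted models assume.
* **Guilds**: unassigned with probability 0.55 (most OTUs, as in real
  FUNGuild output); otherwise drawn from a per-ecogroup distribution
  (default 0.5 on the matched guild, rest uniform), which plants a
  detectable ecogroup–guild association.
* **Scale**: 300 OTUs by default (150 in the acceptance script) so the
  full pipeline runs in minutes on one CPU; the motivating surveys are
  an order of magnitude larger (thousands of OTUs, six-figure library
  sizes) and scale up through the same config.

What it does **not** emulate: spatial autocorrelation within marshes,
taxonomic structure, chimeras/sequencing error, covariate
collinearity between the abiotic and biotic sets, and
season-by-covariate interactions.  Passing tests therefore demonstrate
correctness of the estimators under the assumed generative model, not
robustness to every feature of real surveys.

## Known limitations

* **The transfer ANOVA is anticonservative at the data level.**  Its
  36 cells are not independent: cells sharing a training site (or a
  target site) are correlated, and the in-sample diagonal cells are
  systematically smaller than off-diagonal cells (overfitting), which
  biases the within-region groups downward even when all sites share
  one generative process.  Calibration holds when cell errors are
  exchangeable, which is how the calibration tests exercise it; on
  real nested data the F-test's P-values should be read as
  descriptive, not exact.
* ΔAIC support labels inherit the parameter-count asymmetry described
  above.
* The mixture likelihood is multimodal; n_starts trades time for
  confidence in the global optimum.  G is fixed by design (no
  information-criterion scan across G).
* Rarefaction is a single seeded draw, not an average over draws.
* Wald P-values at the final θ ignore uncertainty in θ itself, as is
  conventional.
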