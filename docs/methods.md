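# Methods

`sparsemet` implements a two-stage genomic-prediction analysis of
multi-environment trials (METs) under sparse testing: instead of
phenotyping every genotype in every environment, each environment
observes only a training set (TRS) of genotypes — some unique to that
environment ("non-overlapping", NOL), some common to all environments
("overlapping", OL) — and mixed models predict the unobserved
genotype-in-environment cells.

## Stage 1: per-environment adjustment

Within each environment (a site × year combination) the plot model is

    y_ijk = mu + L_i + R_j + B_k(R_j) + e_ijk

with genotype `L_i ~ N(0, sigma_L^2)` and incomplete block within
replicate `B_k(R_j) ~ N(0, sigma_BR^2)` random, replicate `R_j` fixed,
and plot error `e_ijk ~ N(0, sigma_e^2)`. Variance components are
estimated by REML: the restricted log-likelihood is profiled over the
error variance and maximized over the two variance ratios
(genotype/error, block/error) with a bounded quasi-Newton search in
log-ratio space from four starts. Log-ratios are bounded in
[-30, 18.4]; the upper bound (ratio ≈ 1e8) makes shrinkage negligible
in noise-free limits while keeping the dense solves well conditioned,
and ratios below 1e-9 are reported as exactly zero (boundary REML — the
non-negativity constraint replaces ad hoc clamping of negative
estimates). BLUPs come from the mixed-model equations at the optimum;
the "adjusted phenotype" of a genotype is `mu-hat + BLUP`, with
`mu-hat` the fixed-effect prediction averaged over replicates.
Entry-mean broad-sense heritability is
`H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)` with `r` replicates,
taking `sigma_g^2` as the stage-1 genotype component — which in a
single-environment analysis absorbs both the genotype main effect and
that environment's share of G×E.

## Stage 2: kernel mixed models

The stage-2 response is the vector of adjusted phenotypes over
(genotype, environment) cells. Three nested Bayesian linear mixed
models share an intercept and i.i.d. Gaussian error:

* **M1 (E + L)** — environment block kernel `Z_E Z_E'` and i.i.d. line
  kernel `Z_g Z_g'`;
* **M2 (E + L + G)** — M1 plus the genomic kernel `Z_g G Z_g'`, where
  `G = XX'/p` is the genomic relationship matrix from the
  column-centered, column-standardized marker matrix `X` (empirical-SD
  scaling with the n−1 denominator; the 2p(1−p) allele-frequency
  scaling is deliberately not used, matching the "centered and
  standardized by columns" convention);
* **M3 (E + L + G + G×E)** — M2 plus the reaction-norm interaction
  kernel `(Z_g G Z_g') ∘ (Z_E Z_E')`: the Hadamard product zeroes
  genomic covariance between cells in different environments, so each
  genotype gets an environment-specific genomic deviation.

Fitting is Gibbs sampling with one variance component per kernel under
scaled-inverse-χ² priors (df0 = 5; prior modes split half the response
variance equally across the kernel terms, the other half going to the
error — the convention of kernel-regression Bayesian software, since
no stronger prior information exists). Each kernel restricted to the
observed cells is eigendecomposed once; effects are parameterized on
the orthonormal eigenbasis, where their joint full conditional is
diagonal and one sweep costs a handful of matrix-vector products.
Eigenvalues below 1e-10 of the largest are treated as null space.
Masked cells are predicted at each retained sweep by the Gaussian
conditional mean `K[masked, observed] K[obs, obs]^+ u`, and
posterior means over retained sweeps are reported. Default chain
settings are 12,000 sweeps, 2,000 burn-in, thinning 5; the evaluation
grid and test suite use shorter chains (typically 1,500/500/5) because
their fits involve a few hundred observed cells with fast-mixing
eigencoordinate updates — effective sample sizes are reported per
component so under-sampling is visible. Variance components may be
pinned (`fixed_components`), which is how the sampler is checked
against the closed-form GLS/BLUP solve.

## Allocation designs

From a random equal partition of all genotypes into one base set per
environment (435/5 = 87 at study scale), a design with TRS size `t`
and `n_ol` overlapping genotypes takes a random `t`-subset of each base
set, drops `n_ol` per environment, and re-observes one common OL set of
`n_ol` drawn from the pooled dropped genotypes. The full design grid
walks NOL down from `t` in steps of 10 to its last positive value and
then 0, over TRS sizes 87…47 — 40 designs in all. Designs with
`n_nol = 0` realize CV1 (every testing genotype is unseen in all
environments); all others realize CV2.

Testing sets are each environment's complement of its *base* partition
set minus the OL genotypes: a predicted cell is never a phenotyped
cell. For all-NOL compositions this gives exactly 348 testing genotypes
per environment at study scale; OL compositions evaluate slightly fewer
(the OL genotypes are excluded from evaluation because they are
observed). The alternative — holding testing sets fixed at the full
base complement — was rejected after an explicit check: it lets
observed OL cells into the evaluation, and that in-sample leakage
reverses the overlap trend in predictive ability.

Predictive ability is the Pearson correlation between predicted and
observed (adjusted) values within each environment; MSE is the mean
squared deviation over the same testing set. Metrics are averaged over
environments within replicate, then over replicates (10 by default,
each with a fresh base partition and fresh NOL/OL draws). Under pure-OL
designs M1 predicts a constant within each environment (unseen
genotypes have an exactly-zero i.i.d. line BLUP), so its correlation is
undefined and recorded as NaN with a note.

## Synthetic data generator

The generator emulates the structure of a cassava MET: 435 genotypes ×
5 environments, ~2,984 post-QC SNPs, an alpha-lattice layout with two
replications analyzed as incomplete blocks nested in replicates.

* **Markers** — per-marker minor allele frequency uniform on a
  configurable range (default 0.05–0.5); genotype classes 0/1/2 drawn
  from Hardy–Weinberg proportions (0 = minor homozygote); missing
  entries i.i.d. No linkage disequilibrium, QTL architecture, or
  population structure is simulated — so the GRM is close to an
  identity plus Wishart noise, which makes separating the i.i.d. line
  component from the genomic component harder than in real structured
  germplasm; variance-recovery checks therefore compare against
  realized (drawn) variances.
* **Genetic values** — genotype main effects by marker regression
  `g = Xb` with i.i.d. Gaussian effects scaled so `var(g) = sigma_g^2`
  (the GBLUP prior); interaction deviations drawn per environment from
  `N(0, sigma_gxe^2 G)`, independent across environments. This makes M3
  the correctly specified model, so parameter recovery is well posed.
  The per-cell value is exactly the sum of its stored components.
* **Plots** — each cell yields `n_replicates` records: cell value +
  fixed replicate effect (drawn once per environment × replicate,
  centered, SD 0.25 by default) + block effect (blocks randomized and
  balanced within replicate; a resolvable alpha design is not
  constructed because the analysis model only uses block-in-rep
  structure) + plot error.
* **Defaults** — two traits on the cassava scale: dry matter `dm`
  (means 29.84–37.31 g across environments, genetic variances
  4.5 + 1.2, target H² 0.83) and fresh root yield `fyld` (means
  17.21–30.44 kg, variances 22 + 9, target H² 0.70). Plot error
  variances are derived from the heritability targets via
  `sigma_e^2 = r * sigma_genetic^2 * (1 - H^2) / H^2` using the
  within-environment genetic variance (main + interaction), since a
  per-environment analysis cannot separate the two; block variances are
  a modest fraction of the plot error. No reference values exist for
  the plot-level residual or block variances, so these defaults are
  chosen to reproduce the heritability range, not any raw dataset.

What passing tests on this generator do **not** show: robustness to LD
structure, family stratification, spatial field trends, or non-Gaussian
trait architecture — none of which are simulated.

## Problem sizes and numerical choices

* Stage-1 REML is validated against a coarse-to-fine grid search
  (final step 1e-3 on both variance ratios) of an independently coded
  error-contrast restricted likelihood.
* The fixed-variance sampler check uses a 20-genotype toy and a direct
  GLS/BLUP linear solve, with agreement required within 1% of the
  response SD.
* M3 variance recovery runs at 300 genotypes × 5 environments with
  components of similar magnitude, 10 replicates, chains 2,500/500/5;
  line, genomic, interaction and error components must sit within 25%
  of realized truth in the median. The environment component is not
  held to that tolerance: five environment draws give its realized
  variance only 4 degrees of freedom (sampling CV ≈ 63%), so no
  estimator can pin it to 25%.
* The qualitative sparse-testing trends run on a reduced grid — 100
  genotypes × 5 environments, substantial G×E
  (sigma_g^2 = sigma_gxe^2 = 1.5, H² = 0.8), TRS rows 20/15/10 with
  compositions {all-NOL, half, all-OL}, 10 replicates, chains
  1,500/500/5 — sizes chosen so the whole suite runs on one CPU in a
  few minutes. Trends are asserted by one-sided sign tests (α = 0.05)
  on replicate means: predictive ability decreasing in overlap
  (M2/M3), MSE increasing in overlap (all models), predictive ability
  increasing in TRS size, and the model ordering M3 ≥ M2 ≥ M1 on the
  subgrid where all three models are defined.

## Known limitations

* Stage 2 ignores the precision of stage-1 adjusted means (no
  weighting); heterogeneous within-environment error variances
  propagate unweighted.
* The i.i.d.-marker GRM limits line/genomic separability; with real
  structured germplasm the genomic component is better identified.
* Reported environment-variance posteriors are prior-influenced
  whenever the number of environments is small.
* No spatial or row-column field models, no marker-effect (Bayes
  A/B/LASSO) alternatives, no environmental-covariate reaction norms.
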