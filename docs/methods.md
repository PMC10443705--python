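# Methods

`gpsel` automates genomic prediction (GP): predicting phenotypes or
breeding values from genome-wide biallelic marker data, and choosing among
candidate statistical and machine-learning models by cross-validated
search.  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the simulation-based tests do
and do not demonstrate.

## Marker encodings

Genotypes are alternate-allele dosages g ∈ {0, 1, 2} (heterozygote = 1).
Three encodings are available, all fitted on training samples only and
frozen for prediction:

* **One-hot**: three indicator columns per marker.
* **Van Raden centering**: Z_ij = g_ij − 2p_j with p_j the training allele
  frequency.  This is the centering used before relationship-matrix and
  distance computation; per-marker variance standardisation
  (division by √(2p_j q_j)) is available behind a flag but off by default,
  because the centered-only form is what the GRM normalisation below
  expects.
* **NOIA additive/dominance**: the orthogonal parameterisation under
  *observed* genotype frequencies (p00, p01, p11).  Additive codes are
  g − (p01 + 2p11); dominance codes are −2p01p11/d, 4p00p11/d, −2p00p01/d
  with d = p00 + p11 − (p00 − p11)².  Both are frequency-weighted mean
  zero and mutually orthogonal, so additive and dominance variance
  components do not contaminate each other.  A marker with d below 1e-8,
  or with no observed heterozygotes, carries no dominance contrast; its
  dominance column is dropped with a warning rather than erroring, since
  such markers are common in biparental families.

Missing genotypes are imputed with the per-marker mode of observed calls
(ties toward the lower dosage) — deterministic and adequate at the
missingness levels of array/GBS data; reference-panel imputation is out of
scope.

**Relationship matrices.** The Van Raden GRM is ZZ′ / (2Σp_jq_j); on a
Hardy–Weinberg population its mean diagonal is ≈1, which the tests check
at n=500, m=1000.  Manhattan and Euclidean distances are computed on the
centered Z.  NOIA additive/dominance kernels are H_AH_A′ and H_DH_D′, each
divided by its mean diagonal; epistasis kernels are the Hadamard products
G_A⊙G_A, G_A⊙G_D, G_D⊙G_D, again rescaled to mean diagonal one.  The
mean-diagonal normaliser puts every kernel on a comparable scale so a
single prior-variance rule can serve all of them; positive
semi-definiteness of the products is guaranteed by the Schur product
theorem.

## Marker selection

Three scorers rank markers; the top k are kept, with ties broken toward
the smaller marker identifier and the selected set returned in input
order.

* **MAF**: minor-allele frequency closest to 0.5 (most informative under a
  purely allele-frequency criterion).
* **MultiSURF**: Relief-family scoring with a per-instance adaptive
  neighbourhood: instance i's threshold is its mean distance to all other
  instances, with a dead-band of half the standard deviation of those
  distances; everything nearer than threshold − dead-band is a neighbour.
  Distances are range-normalised Manhattan (the Relief convention).
  Classification scoring subtracts feature differences for same-class
  neighbours and adds them (with the class-frequency correction
  P(other)/(1 − P(own))) for different-class neighbours.  The published
  algorithm is classification-only; for continuous targets we use the
  RReliefF probability-weighted form with the "different target"
  probability taken as |y_i − y_j| scaled by the target range within the
  neighbourhood — an explicit extension, flagged as such.  The minibatched
  implementation partitions only the *target* instances into shuffled
  batches; thresholds and neighbours are always computed against the full
  dataset, so batching is purely a memory-control device and the scores
  are exactly (to floating-point associativity) those of the brute-force
  reference at any batch size.
* **LMM association scan**: a two-stage kinship-corrected genome scan.
  Stage 1 fits the null model y = Wα + u + ε, u ~ N(0, σ²_g K),
  ε ~ N(0, σ²_e I) by REML, eigendecomposing the Van Raden kinship K once
  and profiling the variance ratio δ = σ²_g/σ²_e by 1-D optimisation
  (coarse grid over log δ ∈ [−10, 10], then bounded refinement).  Stage 2
  tests each marker by generalised least squares with δ held fixed — the
  EMMAX approximation — reporting β̂, SE, the squared-t Wald statistic and
  a Student-t p-value with n − c − 1 degrees of freedom.  With K = I and
  an intercept-only design this reduces *exactly* to the per-marker OLS
  t-test, which is the oracle the tests exploit.  The scan is a ranking
  device for feature selection, so no multiple-testing correction is
  applied.  When used inside the pipeline the scan receives the first
  three principal components of the centered markers (and one-hot
  grouping factors, if present) as covariates.

Selection, like every transform, is fitted per training fold; fitted
selector objects carry their marker lists, so validation samples cannot
influence selection by construction.

## Feature engineering

Up to six named blocks are assembled in a canonical order (markers,
marker_distance, marker_nonlinear, groups, covariates, interactions):

* **Distance features**: each sample's row of the similarity/distance
  matrix with columns anchored to the training samples, which is what
  makes an n×n matrix usable as features for unseen samples.
* **Nonlinear features**: Nyström landmark approximation of an RBF,
  Laplacian or degree-2 polynomial kernel on the Van Raden-scaled markers
  (landmarks sampled without replacement, whitened by the landmark
  kernel's inverse square root).  With landmarks = all training rows the
  feature Gram reproduces the exact kernel to 1e-6.  Default bandwidth
  γ = 1/(q·var(Z)).
* **Scalers**: distance and nonlinear features are quantile-mapped to a
  standard normal (1000 reference quantiles, linear interpolation, new
  data clipped to the fitted range); covariates use z-score, robust
  (median/IQR) or quantile scaling.  The z-score uses the sample (n−1)
  standard deviation, so [1, 2, 3] maps to [−1, 0, 1].  Constant columns
  scale to zeros/medians with a warning.
* **ANOVA-f reduction**: the k best columns of each engineered block by
  univariate F (linear F for regression, one-way F for classification).
* **Grouping factors**: one-hot indicators or their first k principal
  components; unseen levels at prediction time map to all-zero rows.
* **Polynomial covariates**: all monomials to total degree ≤ 3.
* **Interactions**: optionally, the same kernel machinery applied to the
  assembled table, quantile-scaled.

Family constraints at assembly: tree models receive raw (unscaled)
features and no nonlinear/interaction blocks; SVMs skip
nonlinear/interaction blocks (their own kernel covers these); k-NN
excludes distance features.  Constant columns are dropped post-assembly.

## Target transforms and ranking

Regression targets may be z-scored or quantile-mapped to normal or
uniform; transforms are exactly invertible and predictions are reported in
original units, so Pearson scores are comparable across transforms.
Ranking tasks can additionally use (a) a cumulative-distribution ordinal
scheme — K binary classifiers at evenly spaced target quantiles
(default K = min(10, distinct − 1)), score = Σ_k P̂(y > t_k|x) — or (b) a
pairwise scheme in which a scorer is trained to classify whether sample i
outranks sample j under the logistic pairwise loss
ℓ = BCE(σ(s_i − s_j), 1{y_i > y_j}); tied pairs carry no gradient either
way and are excluded with a logged count.  The gradient-boosted-tree
scorer is the canonical consumer of the pairwise path (neural rankers are
out of scope).

## Bayesian engine

A single Gibbs sampler handles multi-block models
y = Σ_b f_b + ε: flat-prior fixed effects, BRR, BayesA, BayesC, Bayesian
LASSO marker blocks and RKHS kernel blocks.  All coefficient updates are
single-site with residual bookkeeping (numba-compiled inner loops);
variance updates are conjugate draws.  Conventions:

* scaled-inv-χ²(df, S) is parameterised so a draw is df·S/χ²(df) with
  mean S·df/(df − 2); df = 5 everywhere by default.
* Default prior scales follow a variance-share rule: each random block's
  prior expected contribution is R²₀/n_blocks of var(y) with R²₀ = 0.5
  (splitting evenly across blocks; BayesC divides by the prior inclusion
  mean π₀ = 5/50; the Bayesian LASSO sets its Gamma(1.1, ·) prior on λ²
  so 2σ²_e/λ² matches the same share).  σ²_e starts at half var(y).
* BayesC: Bernoulli inclusion from the exact marginal-likelihood odds,
  common slab variance, π ~ Beta(5, 45) (≈10% prior inclusion); π can be
  frozen, and forcing π = 1 recovers BRR — an identity the tests assert.
* Bayesian LASSO: Park–Casella coupling β_j ~ N(0, σ²_e τ²_j), with the
  inverse-Gaussian conditional for 1/τ²_j and the β′D⁻¹β term included in
  the σ²_e update.
* RKHS: kernels are eigendecomposed once (components below 1e-8·λ_max
  dropped); the block becomes a ridge block on U√D, so a linear kernel
  ZZ′/c is *exactly* GBLUP and matches BRR on Z (RR-BLUP duality, also
  asserted).  Prediction for new samples uses the cross-kernel and the
  eigen-floor pseudo-inverse: ĝ_new = K_new,train K⁺ ĝ_train.
* Default chains are 6000 iterations, 1000 burn-in, thin 5 for standalone
  fits; the sklearn front-end uses 3000/500/5 and pipeline-search trials
  use shorter chains (1200/300/3) because the search only needs score
  rankings, with the final refit free to use longer chains.  Divergent
  states (non-finite residual variance) abort with a diagnostic rather
  than silently continuing.
* A per-iteration genomic heritability var(g_t)/(var(g_t) + σ²_e,t) is
  tracked from the current genetic fit, giving the posterior h² estimate
  checked by the parameter-recovery test.

Determinism: one seed drives both the numba RNG (coefficient draws) and a
numpy Generator (variance draws); identical (data, config, seed) give
bit-identical chains.

## Model zoo and search

Non-Bayesian families — k-NN, random forest, extra trees, SVR, SGD-fit
penalised linear models (LASSO/ridge/elastic net), LARS, LASSO-LARS,
XGBoost — are library-backed behind a uniform fit/predict contract with
documented, finite hyperparameter bounds.  The SGD estimator standardises
its inputs internally (SGD is scale-sensitive) with learning-rate schedule
"adaptive", η₀ = 0.001, chosen for stability on correlated kernel
features while still matching OLS to 1e-3 when the penalty is tiny.  NGB
is an experimental internal family: gradient boosting of a Gaussian
likelihood where each stage fits the Fisher-preconditioned (natural)
gradient of the mean and log-scale.  LARS-type solvers have no ranking
analogue and are excluded from ranking tasks.

The optimiser draws trial configurations from the joint preprocessing ×
model space and scores them by k-fold cross-validation (default 5-fold;
grouped folds keep every member of a family in one fold and are the
default for the unbalanced design, preventing full siblings from
straddling the train/validation split).  Degenerate (zero-variance)
predictions score 0 with a warning since the correlation is undefined.
Two built-in samplers avoid any external optimiser dependency: pure random
and a TPE-style sampler that, after 8 successful trials, splits history
into the top quartile and the rest, scores 20 random candidates by the sum
of 1-D Parzen (numeric, log-scale where appropriate) or Laplace-smoothed
frequency (categorical) density ratios, and proposes the best candidate.
Ties in the best score go to the earliest trial; the winning configuration
is refit on all data.

`compare_families` runs the search per family on identical folds and
reports the best cross-validated Pearson per family per dataset, plus the
mean LMM-vs-ML gap.

## Simulator

The simulator is the ground truth for every accuracy claim:

* **Founders**: haplotypes from a first-order Markov chain along each
  chromosome — the allele is copied from the previous locus with
  probability exp(−λ·Δd) (λ = `ld_decay` per Morgan, default 20), else
  redrawn at the locus frequency (uniform 0.1–0.9).  This produces
  linkage disequilibrium that decays monotonically with map distance,
  which is the property GP relies on; it is not a coalescent model and
  makes no claim about realistic allele-frequency spectra or recombination
  hotspots.
* **Meiosis**: Poisson(map length) crossovers at uniform map positions,
  strand alternation, independent assortment across chromosomes.
  Defaults: 10 chromosomes × 100 markers, 1 Morgan each.
* **Designs**: `mixed` — progeny of uniformly random non-self crosses
  among 40 parents (default n = 500); `unbalanced` — five biparental
  full-sib families with uneven sizes (default 200/100/50/25/10).  Single
  generation, no selection.
* **Traits**: `n_qtl` (default 100) markers sampled among segregating
  loci, additive effects N(0, 1), optional dominance deviations
  `dominance_degree`·|additive| at heterozygotes; noise variance set from
  the realised genetic variance to hit the target h² (default 0.5), so
  the realised ratio matches to sampling error (±0.05 at n = 1000 in the
  tests).

What passing the simulation tests shows — and does not.  They show the
estimators recover signal of known architecture under the stated
population structures, that heritability estimates are calibrated there,
and that the full pipeline is leak-free and reproducible.  They do not
show performance on real crops: real data have non-Markovian LD,
selection history, genotype-by-environment structure, epistatic
architectures and ascertainment-biased marker panels, none of which the
generator emulates.

## Problem sizes in the shipped checks

The acceptance script runs the sampler identities at the sizes quoted
above (ridge check: n=100, q=50, 20k iterations; recovery: 20 seeds of
n=500, m=1000), and the family comparison at a deliberately desk-scale
budget: n≈400 per design, 3-fold CV (grouped for the unbalanced design),
6 trials per family, shortened search chains.  These sizes are the
package's own benchmark defaults; the comparison's LMM-vs-ML gap at this
budget is reported for inspection rather than asserted, because its sign
is sensitive to the sampled population and trial budget.

## Known limitations

* Univariate targets only; no multi-trait or multi-environment modelling
  beyond one-hot grouping factors.
* BayesB is not implemented; the Bayesian LASSO uses the coupled
  Park–Casella parameterisation only.
* The MultiSURF regression variant is an extension of a
  classification-only published algorithm (see above).
* The TPE-style sampler treats parameters independently (no joint or
  conditional density modelling).
* Biallelic diploid markers only.
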