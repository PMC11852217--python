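# Methods

## The prediction problem

A herd of n ≈ 500 sows is genotyped at m SNPs and phenotyped for
low-heritability reproduction traits (h² ≈ 0.15–0.21). The task is to
predict the corrected phenotype of unphenotyped animals from markers, and
to compare linear mixed-model predictors (GBLUP, the Bayesian alphabet)
with machine-learning regressors operating on genomic-relationship
features. Because n ≪ m, every stage of the pipeline is a device for
concentrating signal: fixed-effect correction, SNP quality control,
GWAS-ranked density panels, and variance-share weighting of prior loci.

## Phenotype correction

Raw records are corrected with `y = Xb + e`, X holding farrowing year,
month and total litter size (categorical by default; any column can be
declared numeric instead). Records with |e − ē| > 3 SD are removed —
applied once by default, optionally iterated; with only ~500 records a
single pass removes the handful of aberrant entries the screen is meant
for. Residuals are standardised with the n−1 sample SD into `y_c`. All
downstream accuracies are Pearson correlations, so the scale convention is
cosmetic; it is fixed here for reproducibility.

## SNP quality control

Stages run in order on the survivors of the previous stage, PLINK-style:
(1) loci without map positions or on sex chromosomes, (2) call rate < 0.95,
(3) MAF < 0.01, (4) Hardy–Weinberg 1-df chi-square p < 1e-6. The 1-df
chi-square (observed vs expected genotype counts) is the common chip-QC
choice at these sample sizes; the exact test is a known alternative and
would only matter at very low minor-allele counts. The ledger records each
stage's removals so that `final = initial − Σ removals` is auditable.

Imputation concordance is scored per locus as the fraction of individuals
whose dosage (0/1/2) matches a sequenced truth set, with loci binned at the
0.3/0.6/0.9 accuracy thresholds and perfectly-imputed loci flaggable for
retention. The imputation algorithm itself is out of scope; only its
accuracy metric is implemented.

## Association scan and PCA covariates

The scan is marginal least squares of `y_c` on allele dosage plus an
intercept and covariates, computed by projecting covariates out of both
sides (Frisch–Waugh), which reproduces per-SNP OLS exactly. Covariates are
the principal components of the mean-imputed, column-standardised dosage
matrix whose eigenvalues are significant at p < 0.01 under a Tracy–Widom
(β = 1) test.

Two numerical points on the eigenvalue test. First, the TW CDF is evaluated
through Chiani's shifted-gamma approximation (k ≈ 46.446, θ ≈ 0.18605,
shift α ≈ 9.84801), which is accurate to ~1e-3 over the relevant range and
avoids embedding a percentile table. Second, the moment-based estimate of
the effective marker count overshoots by a relative factor of about
(ℓ + n̂)/(ℓ² − n̂) (finite-Wishart trace moments, ℓ = number of
eigenvalues); because the TW fluctuation scale is O(n^−2/3), this small
overshoot alone shifts the statistic by roughly +0.9 TW SDs, so the
estimate is debiased before use. With the correction, the lead-eigenvalue
test is calibrated on structureless genotypes (~1% rejections at p < 0.01);
successive tests of lower eigenvalues are conservative under the null —
correctly so, since after removing a bulk-edge top eigenvalue the next one
interlaces below the fresh-Wishart edge. Components beyond the 50th are not
tested; deep in the spectrum the bulk-edge approximation is meaningless.

Per-SNP variance explained is the marginal-OLS form
`PVE = 2f(1−f)β²/Var(y_c)`, clipped to [0,1]. Density panels take the top-s
SNPs by ascending p with genome-order tie-breaks, so panels of increasing
size are nested by construction.

## Kinship and weighting

The plain GRM is VanRaden method 1 on centred dosages. The weighted form is
`G_w = ZDZ′ / Σ w_j·2f_j(1−f_j)` with D = diag(w); uniform weights
reproduce the plain matrix exactly and the normalisation makes G_w
invariant to rescaling all weights. The weighted set is the union of loci
inside trait-associated database intervals (prior 1) and
genome-wide-significant loci (prior 2, p < 1e-5). Within the weighted set,
weights are proportional to per-SNP PVE and rescaled so the set's share of
`Σ w_j·2f_j(1−f_j)` equals ω (default 0.7); the complement shares 1−ω
uniformly. The proportionality-to-PVE rule pins down a weighting that is
otherwise only qualitatively specified; it reduces to the unweighted matrix
when the weighted set is everything with flat PVE.

## REML

Heritability is estimated by single-component REML for
`y_c = μ + g + e`, `g ~ N(0, G σ_g²)`, worked in the eigenbasis of G so
each iteration is O(n). Updates are average-information with an EM step
whenever the AI candidate (clamped to the parameter floor, with
step-halving) fails to increase the restricted likelihood; convergence is
|Δlogℓ| < 1e-6 within 100 iterations, components floored at 1e-8·Var(y).
When the optimum sits on a boundary (σ_e² → 0 for in-sample-selected
panels, σ_g² → 0 for permuted phenotypes) AI/EM can crawl; the estimator
then switches to a bounded 1-D profile-likelihood search over h², with the
overall scale profiled out analytically. The SE of h² comes from the
inverse AI matrix by the delta method.

A fixture note: GRM-REML estimates the variance of genetic values whose
covariance is the *marker* GRM. When the simulated architecture is very
sparse relative to the panel, the marker GRM mis-specifies that covariance
and the estimate attenuates by ~0.02 at 100 QTL per 2000 loci (measured
over 80 replicates). Heritability-recovery experiments therefore use a
polygenic architecture (QTL at half the loci), under which recovery is
unbiased within Monte-Carlo error.

## GBLUP and the Bayesian alphabet

GBLUP solves the mixed-model equations directly:
`ĝ = σ_g² G V⁻¹(y − 1μ̂)`, `V = σ_g²G + σ_e²I`, μ̂ by GLS; predictions for
query animals use their relationship rows times the stored weights. This is
algebraically kernel ridge regression with kernel G and ridge λ = σ_e²/σ_g²
— asserted to 1e-8 in the tests rather than assumed.

The five Bayesian regressions share the likelihood
`y = 1μ + Xβ + e` (X centred, not standardised, so β stays in dosage units
consistent with the PVE formula) and differ in the prior on β: common
normal variance with a scaled-inverse-χ² prior (BRR); per-locus variances
with a gamma-updated common scale (Bayes A); spike–slab with per-locus slab
variances, beta-updated π and gamma-updated scale (Bayes B); spike–slab
with one common slab variance (Bayes C); and the normal–exponential mixture
with a gamma hyperprior on λ² (Bayesian LASSO). All updates are conjugate
single-site Gibbs; chains are seeded and bit-reproducible. Because `y_c` is
pre-corrected, no fixed effects beyond the intercept enter the samplers —
that is a pipeline contract, not an approximation.

Hyperparameter defaults follow the usual R²-style partition: the prior is
centred so markers explain half of Var(y) (df_β = 5; scale solved from the
summed marker variances; for the spike–slab families divided by the prior
inclusion probability π₀ = 0.5 with effective prior count p₀ = 10; the BL
rate solved the same way). Run control defaults to 5,000 iterations, 1,000
burn-in, thinning 5; the closed-form cross-checks (fixed-variance BRR vs
ridge; Bayes C at π = 1 vs BRR, which match bitwise because the update
sequences coincide) use shorter chains. Chain length, like every other
knob, is surfaced in `MCMCConfig` rather than asserted as a claim about any
particular dataset.

## ML regressors on kinship features

Each animal's feature vector is its GRM row restricted to the training
columns — a relationship profile to the reference population. This is the
pipeline's dimensionality-reduction choice; raw-dosage features remain
available by passing any matrix. The regressors are authored in-package:

- **KRR**: dual solve `(K + λI)⁻¹y`; linear-on-GRM or RBF on GRM rows
  (default γ tuned). The kernel must be symmetric PSD within tolerance.
- **Trees**: CART variance-reduction splits, exact midpoint thresholds or a
  quantile-histogram mode (used by the ensembles for speed on dense
  features; boundaries are bin edges, so histogram and exact trees agree
  closely but not exactly).
- **Random forest**: bootstrap bagging plus per-split feature subsampling;
  prediction is the plain mean of member trees. A single tree with bagging
  and subsampling off reduces exactly to `fit_tree`.
- **GBDT**: squared-loss boosting from the target mean with shrinkage α.
  The GOSS variant keeps the top-a fraction of samples by |residual| plus a
  random b fraction of the rest upweighted by (1−a)/b; a = 1 is bitwise
  plain GBDT. Exclusive feature bundling is deliberately omitted: GRM
  features are dense, and bundling targets sparse one-hot designs.
- **AdaBoost.R2**: weight-resampled rounds; losses normalised to [0,1] by a
  linear (default), square or exponential rule; the round stops when the
  average loss reaches 0.5; prediction is the weighted median with weights
  log(1/ε_t), taking the smallest qualifying value (infimum semantics).
  Numerically perfect fits (max error ≤ 1e-12 of the target scale) are
  treated as zero loss so degenerate targets terminate cleanly.

## Evaluation

Accuracy is the Pearson correlation between predicted and observed `y_c`.
Cross-validation partitions the 400 training animals into five seeded
near-equal folds; the report stores per-fold values so the mean ± SD always
recomputes. Hyperparameters are tuned by maximising CV accuracy with a
Gaussian-process surrogate (Matérn-5/2 on the unit cube, one-of-k for
categoricals, expected-improvement acquisition over random candidates,
seeded); the independent test freezes those hyperparameters, refits on all
400 training animals, and scores the 115 holdout once, with an id-overlap
leakage guard. The one-way ANOVA across traits reports SS/df/MS/F/p and the
5% critical F.

## The synthetic-data generator

Haplotypes come from a block-wise Gaussian-copula threshold model: within a
block of B SNPs (default 20) a latent MVN vector with AR(1) correlation
ρ^|i−j| (default ρ = 0.6) is thresholded at the allele-frequency quantile
(frequencies uniform on [0.05, 0.5]); blocks are independent and two
independent haplotypes per individual make genotypes Hardy–Weinberg by
construction. Traits are additive: QTL effects drawn N(0,1) (or
equal-magnitude random-sign for recovery experiments where every planted
locus must carry detectable signal) and rescaled so the realised genetic
variance is exactly h²; noise variance is 1 − h²; categorical management
effects (year 3, month 12, litter-size class 8 levels, level effects
N(0, 0.5²)) are added on top. Defaults mirror the target design: 515
animals, h² = 0.19, sparse architecture.

What the generator does **not** emulate: family and pedigree structure
(individuals are unrelated), population stratification, genotyping error,
coalescent LD decay, sex chromosomes, and repeated records. Two
consequences matter for interpreting results. First, with unrelated
individuals a full-panel GRM on a very sparse trait carries almost no
predictive signal — prediction must come from panels concentrated on
trait-associated loci, which is exactly the design under study. Second,
passing trend tests here says the pipeline reproduces the *mechanisms*
(selection optimism, noise dilution, weighting stability), not that real
herds would show the same accuracy values, which depend on relatedness the
generator omits.

## The density-panel sweep

`sweep.run_sweep` runs the whole design at desk scale: 515 animals, 10k
loci, 20 QTL at h² = 0.19; GWAS and PVE on the 400 training animals; nested
panels of 1k…9k loci standing in for the full-scale 100k…900k series;
plain and ω = 0.7 weighted GRMs (prior regions cover ~60% of true QTL with
±5 kb intervals, a database-coverage analogue); GBLUP scored by fivefold CV
within the training animals and one independent test on the 115 holdout.
Panel selection reuses the animals CV resamples — the protocol of record
for this design — so CV accuracy carries selection optimism while the
holdout does not. Three qualitative behaviours are asserted over
replicates: mean CV accuracy peaks at an interior panel size (signal
accumulates, then noise dilutes); the weighted GRM's accuracy varies less
across the three largest panels (the causal share is pinned at ω instead of
shrinking with panel size); and the independent test scores below CV.

## Problem sizes

Experiments are sized for a single CPU: recovery runs use 50 replicates at
n = 515 with 2k loci; the sweep uses 6–8 replicates of the 10k-locus
design; samplers use 1,200–6,000 iterations depending on whether a
closed-form comparison needs tight Monte-Carlo error. All sizes are
configuration, not constants.

## Known limitations

- Single-trait, single-variance-component models only; no dominance,
  epistasis, pedigree A-matrix or multi-trait REML.
- The Gibbs samplers are single-site and O(n·m) per sweep in Python; they
  are meant for panels of a few thousand loci, not millions.
- The successive Tracy–Widom procedure is conservative beyond the lead
  eigenvalue; it selects covariate PCs, it does not count structure
  dimensions.
- The exact HWE test and per-individual call-rate filtering are not
  implemented (the 1-df chi-square and per-SNP call rate are).
- The Bayesian optimiser uses fixed GP hyperparameters (lengthscale 0.25 on
  the unit cube); it is built for ≤ a few hundred evaluations.
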