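# swinegp

Genomic prediction of pig reproduction traits — litter weight (LW), total
number born (TNB), number born alive (NBA) — from medium-density SNP data,
for breeders and quantitative geneticists comparing classical mixed-model
predictors with machine-learning regressors on small herds.

The package implements the full analysis pipeline as a tested library:

1. **Synthetic herds** (`simdata`): block-LD genotypes from a Gaussian-copula
   haplotype model, sparse additive QTL traits with configurable narrow-sense
   heritability, management fixed effects, chip-versus-sequence masking.
2. **Phenotype correction** (`pheno`): the fixed-effect model `y = Xb + e`,
   an aberrant-record screen (|e| > 3 SD), and standardisation into the
   unitless corrected phenotype `y_c`.
3. **SNP quality control** (`genoqc`): positional/sex-chromosome, call-rate
   (≥ 0.95), MAF (≥ 0.01) and Hardy–Weinberg (p ≥ 1e-6) stages with an
   auditable removal ledger, plus the per-locus imputation-concordance
   metric.
4. **Association and panels** (`gwas`): single-SNP regression with principal
   component covariates chosen by a Tracy–Widom test (p < 0.01), the per-SNP
   variance share `PVE = 2f(1−f)β²/Var(y_c)`, and nested GWAS-ranked SNP
   density panels.
5. **Kinship and heritability** (`grm`): VanRaden `G = ZZ′ / 2Σf(1−f)`, a
   prior-information weighted `G_w = ZDZ′` whose weighted loci carry a
   configurable share ω (default 0.7) of the marker variance, and
   single-component AI-REML with an EM/profile fallback for `h²`.
6. **Whole-genome regression** (`bayeslin`): GBLUP via the mixed-model
   equations, and Gibbs samplers for Bayes A, Bayes B, Bayes C, the Bayesian
   LASSO and Bayesian ridge regression, differing only in the prior on
   marker effects.
7. **ML regressors** (`mlpred`): kernel ridge regression
   `ŷ = k′(K + λI)⁻¹y`, CART regression trees, random forests, gradient
   boosting with a GOSS sampling variant, and AdaBoost.R2 with the
   weighted-median combination rule — all operating on GRM rows
   (relationship profiles to the training animals) as features.
8. **Evaluation** (`evalopt`, `sweep`): Pearson-r accuracy, seeded fivefold
   cross-validation, Gaussian-process Bayesian hyperparameter optimisation,
   an independent test with a leakage guard, CV/independent consistency, a
   one-way ANOVA across traits, and the end-to-end density-panel sweep.

## Worked example

A sparse trait (20 QTL, h² = 0.19) in a 515-sow herd genotyped at 10k loci;
400 animals train the model, 115 are reserved for an independent test, and
prediction uses GBLUP on a GRM built from the top-1000 GWAS-ranked SNPs:

```python
import numpy as np
import swinegp as sg

cfg = sg.SimConfig(n_individuals=515, n_snps=10_000, n_qtl=20, h2=0.19, seed=7)
geno = sg.simulate_genotypes(cfg)
pheno, truth = sg.simulate_phenotypes(geno, cfg, trait_name="tnb")

cp = sg.correct_trait(pheno, "tnb")          # y = Xb + e, screen, standardise
keep = np.array([geno.sample_ids.index(s) for s in cp.sample_ids])
geno, yc = geno.subset_individuals(keep), cp.yc

clean, ledger = sg.apply_qc(geno)            # staged SNP QC with a ledger

perm = np.random.default_rng(0).permutation(len(yc))
train, hold = np.sort(perm[:400]), np.sort(perm[400:])
res = sg.single_snp_assoc(yc[train], clean.subset_individuals(train))
panel = sg.build_panels(res, [1000])[0]      # GWAS-ranked density panel
sub = clean.subset_snps(panel.genome_order())
G = sg.vanraden_grm(sub)

def gblup_fold(tr, te):
    gi, qi = train[tr], train[te]
    Gt = sg.GRMatrix(G.values[np.ix_(gi, gi)], [G.sample_ids[i] for i in gi])
    fit = sg.fit_gblup(Gt, yc[gi])
    return sg.predict_gblup(fit, G.values[np.ix_(qi, gi)])

rep = sg.kfold_cv(yc[train], gblup_fold, k=5, seed=0, method="gblup")
Gt = sg.GRMatrix(G.values[np.ix_(train, train)], [G.sample_ids[i] for i in train])
fit = sg.fit_gblup(Gt, yc[train])
r_ind = sg.accuracy(sg.predict_gblup(fit, G.values[np.ix_(hold, train)]), yc[hold])
```

Output:

```
corrected records: 513 (2 aberrant removed)
QC: 10000 -> 10000 SNPs
panel: top 1000 SNPs, best p = 1.66e-07
GBLUP fivefold CV: r = 0.870 +/- 0.015
independent test (115 animals): r = 0.136
```

The gap between the cross-validated and independent accuracies is the point:
the panel was ranked on the same 400 animals that CV resamples, so CV
accuracy carries panel-selection optimism, while the 115 holdout animals
measure honest generalisation. `sweep.run_sweep` automates this experiment
across nested panel sizes and weighted/unweighted GRMs.

A thin CLI mirrors the stages for shell use:

```bash
swinegp simulate --n 515 --m 10000 --out herd
swinegp qc --bfile herd --out herd.qc
swinegp correct --pheno herd.pheno.csv --trait trait --out yc.tsv
swinegp gwas --bfile herd.qc --yc yc.tsv --out assoc.tsv
swinegp grm --bfile herd.qc --out herd.g
swinegp reml --grm herd.g --yc yc.tsv
swinegp cv --bfile herd.qc --yc yc.tsv --method gblup
```

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generator and its limits, numerical choices, and known limitations.
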