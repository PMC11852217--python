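"""Synthetic genotype/phenotype generator for the prediction pipeline.

The generator emulates a single closed pig nucleus herd genotyped on a
medium-density chip: biallelic autosomal SNPs organised in LD blocks, a
sparse additive QTL architecture, low-heritability reproduction traits, and
categorical management fixed effects (farrowing year, month, litter size
class).  Haplotypes come from a block-wise Gaussian-copula threshold model:
within a block of size ``B`` a latent MVN vector with AR(1) correlation
``rho^|i-j|`` is thresholded at the allele-frequency quantile, so LD decays
within blocks and blocks are independent.  Sampling two independent
haplotypes per individual makes genotype frequencies Hardy-Weinberg by
construction.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, PhenotypeTable


@dataclass
class SimConfig:
    """Study-design knobs for one simulated population and trait.

    Defaults mirror the design the pipeline targets: ~515 sows, a sparse
    additive architecture, narrow-sense heritability around 0.19, and
    year/month/litter-size management factors.
    """

    n_individuals: int = 515
    n_snps: int = 10_000
    n_chromosomes: int = 18
    ld_block_size: int = 20
    within_block_corr: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 100
    h2: float = 0.19
    fixed_effect_levels: dict[str, int] = field(
        default_factory=lambda: {"year": 3, "month": 12, "litter_size": 8}
    )
    fixed_effect_sd: float = 0.5
    missing_rate: float = 0.0
    #: "normal" draws QTL effects N(0,1) before rescaling; "equal" plants
    #: equal-magnitude random-sign effects (for recovery experiments where
    #: every QTL should carry detectable signal)
    qtl_effect_dist: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_snps <= 0 or self.n_chromosomes <= 0:
            raise ValueError("population dimensions must be positive")
        if self.ld_block_size <= 0:
            raise ValueError("ld_block_size must be positive")
        if not 0.0 <= self.within_block_corr < 1.0:
            raise ValueError("within_block_corr must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.n_qtl <= self.n_snps:
            raise ValueError("n_qtl must lie in [0, n_snps]")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.h2 > 0 and self.n_qtl == 0:
            raise ValueError("h2 > 0 requires at least one QTL (degenerate config)")
        if self.qtl_effect_dist not in ("normal", "equal"):
            raise ValueError("qtl_effect_dist must be 'normal' or 'equal'")


@dataclass
class TraitTruth:
    """Ground truth of one simulated trait, for recovery tests."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_breeding_values: np.ndarray
    realized_h2: float


def _block_cholesky(block_size: int, rho: float) -> np.ndarray:
    idx = np.arange(block_size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a seeded genotype matrix with block LD and HWE genotypes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresholds = stats.norm.ppf(freqs)

    # two haplotypes per individual, block-correlated latent Gaussians
    z = rng.standard_normal(size=(2 * n, m))
    bs = cfg.ld_block_size
    if cfg.within_block_corr > 0.0:
        chol_full = _block_cholesky(bs, cfg.within_block_corr)
        for start in range(0, m, bs):
            stop = min(start + bs, m)
            L = chol_full[: stop - start, : stop - start]
            z[:, start:stop] = z[:, start:stop] @ L.T
    haplo = (z < thresholds).astype(np.int8)
    dosages = haplo[:n] + haplo[n:]

    if cfg.missing_rate > 0.0:
        mask = rng.random(size=dosages.shape) < cfg.missing_rate
        dosages = np.where(mask, MISSING, dosages).astype(np.int8)

    # spread SNPs evenly over autosomes, positions increasing per chromosome
    per_chrom = int(np.ceil(m / cfg.n_chromosomes))
    chroms = np.repeat(np.arange(1, cfg.n_chromosomes + 1), per_chrom)[:m]
    pos = np.concatenate(
        [np.arange(np.sum(chroms == c)) * 1000 + 1000 for c in range(1, cfg.n_chromosomes + 1)]
    )
    snp_meta = pd.DataFrame(
        {
            "chrom": chroms.astype(str),
            "pos": pos.astype(np.int64),
            "snp_id": [f"snp{j}" for j in range(m)],
            "a1": "A",
            "a2": "G",
        }
    )
    sample_ids = [f"ind{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, snp_meta=snp_meta, sample_ids=sample_ids)


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig, trait_name: str = "trait"
) -> tuple[PhenotypeTable, TraitTruth]:
    """Simulate one additive trait on top of ``geno``.

    phenotype = sum of categorical fixed effects + breeding value + noise,
    with QTL effects rescaled so the realised genetic variance is exactly
    ``cfg.h2`` (on a total-variance-1 scale) and noise variance 1 - h2, so
    Var(g)/Var(g+e) = h2 in expectation.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E3779B9]))
    n = geno.n_individuals

    qtl_idx = np.sort(rng.choice(geno.n_snps, size=cfg.n_qtl, replace=False))
    X_qtl = geno.dosages[:, qtl_idx].astype(np.float64)
    if np.any(X_qtl < 0):
        raise ValueError("QTL columns must be complete (no missing dosages)")

    if cfg.qtl_effect_dist == "equal":
        effects = rng.choice([-1.0, 1.0], size=cfg.n_qtl)
    else:
        effects = rng.standard_normal(cfg.n_qtl)
    g0 = X_qtl @ effects
    sd0 = np.std(g0)
    if cfg.h2 > 0 and sd0 == 0:
        raise ValueError("degenerate config: zero genetic variance with h2 > 0")
    scale = np.sqrt(cfg.h2) / sd0 if sd0 > 0 else 0.0
    effects = effects * scale
    g = X_qtl @ effects

    noise = rng.standard_normal(n) * np.sqrt(1.0 - cfg.h2)

    fixed_total = np.zeros(n)
    covars: dict[str, np.ndarray] = {}
    for name, n_levels in cfg.fixed_effect_levels.items():
        levels = rng.integers(0, n_levels, size=n)
        level_eff = rng.standard_normal(n_levels) * cfg.fixed_effect_sd
        fixed_total += level_eff[levels]
        covars[name] = levels

    phen = fixed_total + g + noise
    var_e = np.var(noise)
    realized_h2 = float(np.var(g) / (np.var(g) + var_e)) if (np.var(g) + var_e) > 0 else 0.0

    data = pd.DataFrame({"sample_id": geno.sample_ids, trait_name: phen, **covars})
    # all generated factors are class variables (litter size enters as a
    # class, so the correction model matches the generating model)
    table = PhenotypeTable(
        data=data,
        trait_cols=[trait_name],
        categorical_covariates=list(covars),
        numeric_covariates=[],
    )
    truth = TraitTruth(
        qtl_indices=qtl_idx,
        qtl_effects=effects,
        true_breeding_values=g,
        realized_h2=realized_h2,
    )
    return table, truth


def mask_to_chip(
    geno: GenotypeMatrix, keep_fraction: float, seed: int
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Down-sample SNPs to a chip-density panel; returns (chip, truth).

    Emulates a chip-versus-sequence design: the chip panel is a uniform
    random subset of loci, the second element is the untouched full matrix.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    m = geno.n_snps
    n_keep = int(round(keep_fraction * m))
    keep = np.sort(rng.choice(m, size=n_keep, replace=False))
    return geno.subset_snps(keep), geno
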