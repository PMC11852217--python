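"""GBLUP and the Bayesian alphabet as single-site Gibbs samplers.

All five whole-genome regression models share the likelihood
``y = 1 mu + X beta + e`` with centred dosage columns X and differ only in
the prior on marker effects:

* ``BRR``  - one common normal variance, scaled-inverse-chi-square prior.
* ``A``    - per-locus variances, common scale with a gamma hyperprior.
* ``B``    - spike-slab with per-locus slab variances and a beta prior on
             the inclusion probability pi.
* ``C``    - spike-slab with one common slab variance.
* ``BL``   - Bayesian LASSO: normal-exponential mixture with a gamma
             hyperprior on lambda^2.

Updates are fully conjugate; chains are seeded and bit-reproducible.
Hyperparameter defaults follow the usual R2-style partition: the prior is
centred so markers explain half the phenotypic variance unless told
otherwise.

GBLUP is solved directly from the mixed-model equations with variance
components from REML (or supplied), and is algebraically a kernel ridge
regression with kernel G and ridge sigma_e2/sigma_g2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix, GRMatrix
from .grm import reml_h2

FAMILIES = ("A", "B", "C", "BL", "BRR")


@dataclass
class PriorSpec:
    """Prior family and hyperparameters for one Bayesian alphabet member."""

    family: str = "BRR"
    df_beta: float = 5.0
    s_beta: float | None = None  # solved from r2_prior when None
    pi0: float = 0.5  # prior mean inclusion probability (B, C)
    p0: float = 10.0  # prior effective count for pi
    r2_prior: float = 0.5  # share of var(y) assigned to markers a priori
    shape_s: float = 1.1  # gamma hyperprior shape on S_beta (A, B) / lambda^2 (BL)

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.df_beta <= 0:
            raise ValueError("df_beta must be positive")
        if not (0 < self.pi0 < 1 and self.p0 > 0):
            raise ValueError("beta-prior parameters must be positive, pi0 in (0,1)")
        if not 0 < self.r2_prior < 1:
            raise ValueError("r2_prior must lie in (0, 1)")


@dataclass
class MCMCConfig:
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 5
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class BayesFit:
    family: str
    mu: float
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    sigma_e2_mean: float
    sigma_beta2_mean: float
    inclusion_prob: np.ndarray | None
    fitted: np.ndarray
    centers: np.ndarray
    snp_ids: list[str]
    n_draws: int


@dataclass
class GblupFit:
    mu: float
    sigma_g2: float
    sigma_e2: float
    gebv: np.ndarray
    alpha: np.ndarray  # sigma_g2 * V^-1 (y - 1 mu); prediction weights
    sample_ids: list[str] = field(default_factory=list)

    @property
    def fitted(self) -> np.ndarray:
        return self.mu + self.gebv


def fit_gblup(
    G: GRMatrix, yc: np.ndarray, varcomp: tuple[float, float] | None = None
) -> GblupFit:
    """Mixed-model GBLUP solve; variance components by REML if not given.

    ``varcomp`` is (sigma_g2, sigma_e2).  GEBVs are
    ``g = sigma_g2 G V^-1 (y - 1 mu)`` with ``V = sigma_g2 G + sigma_e2 I``
    and mu the GLS mean.  Prediction for new individuals uses their
    relationship rows times the stored alpha weights.
    """
    y = np.asarray(yc, dtype=np.float64)
    if y.size != G.n:
        raise ValueError("phenotype length does not match GRM order")
    if varcomp is None:
        res = reml_h2(G, y)
        sg, se = res.sigma_g2, res.sigma_e2
    else:
        sg, se = varcomp
        if sg <= 0 or se < 0:
            raise ValueError("variance components must be positive (sigma_e2 >= 0)")
    n = y.size
    V = sg * G.values + se * np.eye(n)
    try:
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, np.ones(n))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular V; applying 1e-6 ridge", stacklevel=2)
        V = V + 1e-6 * np.trace(V) / n * np.eye(n)
        Vinv_y = np.linalg.solve(V, y)
        Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(np.sum(Vinv_y) / np.sum(Vinv_1))
    alpha = sg * np.linalg.solve(V, y - mu)
    gebv = G.values @ alpha
    return GblupFit(
        mu=mu, sigma_g2=float(sg), sigma_e2=float(se), gebv=gebv, alpha=alpha,
        sample_ids=list(G.sample_ids),
    )


def predict_gblup(fit: GblupFit, G_cross: np.ndarray) -> np.ndarray:
    """Predictions for query individuals from their G rows vs training."""
    G_cross = np.atleast_2d(np.asarray(G_cross, dtype=np.float64))
    if G_cross.shape[1] != fit.alpha.size:
        raise ValueError("G_cross columns must match the training set")
    return fit.mu + G_cross @ fit.alpha


def _scaled_inv_chi2(rng: np.random.Generator, df: float, ss: float) -> float:
    return ss / rng.chisquare(df)


def fit_bayes(
    geno_panel: GenotypeMatrix,
    yc: np.ndarray,
    prior: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    fixed_sigma_e2: float | None = None,
    fixed_sigma_beta2: float | None = None,
    fixed_pi: float | None = None,
) -> BayesFit:
    """Gibbs sampler for one Bayesian alphabet member.

    ``fixed_*`` arguments freeze the corresponding parameter (no update),
    which turns BRR into a ridge model with known variances and Bayes C
    with ``fixed_pi=1`` into BRR - both used as closed-form cross-checks.
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    prior.validate()
    mcmc.validate()
    rng = np.random.default_rng(mcmc.seed)

    X = np.asfortranarray(geno_panel.dosages_float(impute_mean=True))
    centers = X.mean(axis=0)
    X -= centers
    y = np.asarray(yc, dtype=np.float64)
    n, p = X.shape
    if y.size != n:
        raise ValueError("phenotype length does not match genotype rows")
    xtx = np.einsum("ij,ij->j", X, X)
    xtx = np.where(xtx <= 0, 1e-12, xtx)
    cols = [np.ascontiguousarray(X[:, j]) for j in range(p)]

    var_y = max(float(np.var(y, ddof=1)), 1e-12)
    vx = float(np.sum(xtx) / (n - 1))  # summed marker variances
    r2 = prior.r2_prior
    dfb = prior.df_beta
    # residual prior: mode at (1 - r2) var(y)
    dfe = 5.0
    s_e = (1.0 - r2) * var_y * (dfe + 2.0)

    fam = prior.family
    spike = fam in ("B", "C")
    pi = prior.pi0 if fixed_pi is None else fixed_pi
    # prior mode of sigma_beta2 so that markers explain r2 var(y)
    target_vb = max(r2 * var_y / max(vx, 1e-12), 1e-12)
    if spike:
        target_vb = target_vb / pi
    s_b = prior.s_beta if prior.s_beta is not None else target_vb * (dfb + 2.0)
    lam2 = 2.0 * (1.0 - r2) * vx / (r2 * max(var_y, 1e-12))  # BL rate init
    lam2_shape0, lam2_rate0 = prior.shape_s, prior.shape_s / max(lam2, 1e-12)
    sb_shape0, sb_rate0 = prior.shape_s, (prior.shape_s - 1.0) / max(s_b, 1e-12)

    mu = float(np.mean(y))
    beta = np.zeros(p)
    delta = np.ones(p, dtype=bool)
    sigma_e2 = fixed_sigma_e2 if fixed_sigma_e2 is not None else (1.0 - r2) * var_y
    if fam in ("A", "B"):
        sigma_b2 = np.full(p, target_vb)
    else:
        sigma_b2 = np.array([fixed_sigma_beta2 or target_vb])
    if fixed_sigma_beta2 is not None:
        sigma_b2 = np.full_like(sigma_b2, fixed_sigma_beta2)
    tau2 = np.full(p, 2.0 / max(lam2, 1e-12))  # BL local scales

    r = y - mu - X @ beta

    sum_beta = np.zeros(p)
    sum_beta2 = np.zeros(p)
    sum_delta = np.zeros(p)
    sum_mu = 0.0
    sum_se = 0.0
    sum_sb = 0.0
    sum_fit = np.zeros(n)
    n_draws = 0

    for it in range(mcmc.n_iter):
        # intercept
        mu_new = mu + np.mean(r) + rng.standard_normal() * np.sqrt(sigma_e2 / n)
        r -= mu_new - mu
        mu = mu_new

        log_odds_base = np.log(pi) - np.log1p(-pi) if spike and pi < 1.0 else np.inf

        for j in range(p):
            xj = cols[j]
            bj = beta[j]
            rhs = xj @ r + xtx[j] * bj
            if fam == "BL":
                prior_prec = 1.0 / tau2[j]
            elif fam in ("A", "B"):
                prior_prec = sigma_e2 / sigma_b2[j]
            else:
                prior_prec = sigma_e2 / sigma_b2[0]
            cj = xtx[j] + prior_prec
            if spike:
                vb = sigma_b2[j] if fam == "B" else sigma_b2[0]
                if pi >= 1.0:
                    inc = True
                else:
                    log_lr = 0.5 * (
                        np.log(sigma_e2 / (vb * xtx[j] + sigma_e2))
                        + rhs**2 / (sigma_e2 * cj)
                    )
                    lo = log_odds_base + log_lr
                    inc = rng.random() < 1.0 / (1.0 + np.exp(-lo))
                delta[j] = inc
                if inc:
                    bnew = rhs / cj + rng.standard_normal() * np.sqrt(sigma_e2 / cj)
                else:
                    bnew = 0.0
            else:
                bnew = rhs / cj + rng.standard_normal() * np.sqrt(sigma_e2 / cj)
            if bnew != bj:
                r -= xj * (bnew - bj)
                beta[j] = bnew

        # local scales / variances (floored to keep precisions finite)
        if fixed_sigma_beta2 is None:
            if fam == "A":
                sigma_b2 = (beta**2 + s_b * dfb) / rng.chisquare(dfb + 1.0, size=p)
                s_b = rng.gamma(
                    sb_shape0 + 0.5 * p * dfb,
                    1.0 / (sb_rate0 + 0.5 * dfb * np.sum(1.0 / sigma_b2)),
                )
            elif fam == "B":
                add = np.where(delta, beta**2, 0.0)
                sigma_b2 = (add + s_b * dfb) / rng.chisquare(
                    dfb + delta.astype(float), size=p
                )
                s_b = rng.gamma(
                    sb_shape0 + 0.5 * p * dfb,
                    1.0 / (sb_rate0 + 0.5 * dfb * np.sum(1.0 / sigma_b2)),
                )
            elif fam == "C":
                k = int(delta.sum())
                ss = float(np.sum(beta[delta] ** 2)) + s_b * dfb
                sigma_b2[0] = _scaled_inv_chi2(rng, dfb + k, ss)
            elif fam == "BRR":
                ss = float(np.sum(beta**2)) + s_b * dfb
                sigma_b2[0] = _scaled_inv_chi2(rng, dfb + p, ss)
            elif fam == "BL":
                b2 = np.maximum(beta**2, 1e-20)
                inv_tau2 = rng.wald(np.sqrt(lam2 * sigma_e2 / b2), lam2)
                tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
                lam2 = rng.gamma(
                    lam2_shape0 + p, 1.0 / (lam2_rate0 + 0.5 * np.sum(tau2))
                )

        if fixed_sigma_beta2 is None:
            sigma_b2 = np.maximum(sigma_b2, 1e-14)

        if spike and fixed_pi is None:
            k = int(delta.sum())
            pi = rng.beta(prior.p0 * prior.pi0 + k, prior.p0 * (1 - prior.pi0) + p - k)

        if fixed_sigma_e2 is None:
            ss = float(r @ r)
            if fam == "BL":
                # beta | tau2 scales with sigma_e2 in the BL parametrisation
                ss += float(np.sum(beta**2 / tau2))
                sigma_e2 = max(_scaled_inv_chi2(rng, n + p + dfe, ss + s_e), 1e-14)
            else:
                sigma_e2 = max(_scaled_inv_chi2(rng, n + dfe, ss + s_e), 1e-14)

        if not np.isfinite(sigma_e2) or not np.all(np.isfinite(beta)):
            raise RuntimeError(f"divergent chain at iteration {it}")

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            n_draws += 1
            sum_beta += beta
            sum_beta2 += beta**2
            sum_delta += delta
            sum_mu += mu
            sum_se += sigma_e2
            sum_sb += float(np.mean(sigma_b2)) if fam != "BL" else float(
                sigma_e2 * np.mean(tau2)
            )
            sum_fit += mu + (y - mu - r) - 0.0  # mu + X beta == y - r

    if n_draws == 0:
        raise ValueError("no posterior draws retained; check burn_in/thin")
    bm = sum_beta / n_draws
    bsd = np.sqrt(np.maximum(sum_beta2 / n_draws - bm**2, 0.0))
    return BayesFit(
        family=fam,
        mu=sum_mu / n_draws,
        beta_mean=bm,
        beta_sd=bsd,
        sigma_e2_mean=sum_se / n_draws,
        sigma_beta2_mean=sum_sb / n_draws,
        inclusion_prob=(sum_delta / n_draws) if spike else None,
        fitted=sum_fit / n_draws,
        centers=centers,
        snp_ids=list(geno_panel.snp_meta["snp_id"]),
        n_draws=n_draws,
    )


def predict_bayes(fit: BayesFit, geno_new: GenotypeMatrix) -> np.ndarray:
    """mu + centred dosages times posterior-mean effects."""
    if list(geno_new.snp_meta["snp_id"]) != fit.snp_ids:
        raise ValueError("SNP panel of geno_new does not match the training panel")
    Xn = geno_new.dosages_float(impute_mean=True) - fit.centers
    return fit.mu + Xn @ fit.beta_mean
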