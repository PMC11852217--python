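"""Association scan, PCA covariate selection, and SNP panel design.

The scan is a single-marker fixed-effect regression of the corrected
phenotype on allele dosage plus covariates (typically significant genotype
principal components).  Principal components are selected by testing each
leading eigenvalue of the standardised genotype covariance against the
Tracy-Widom null, EIGENSTRAT-style.  Panels of increasing density are built
by ranking loci on association p-value, which makes them nested by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

# Tracy-Widom (beta=1) CDF via the shifted-gamma approximation of Chiani
# (2014): TW1 + alpha ~ Gamma(k, theta).  Accurate to ~1e-3 over the body
# and tails used for eigenvalue testing.
_TW1_K = 46.44604884387132
_TW1_THETA = 0.18605402228279955
_TW1_ALPHA = 9.848007781128567


def tracy_widom_sf(x: np.ndarray | float) -> np.ndarray | float:
    """Upper-tail probability of the Tracy-Widom (beta=1) distribution."""
    return stats.gamma.sf(np.asarray(x) + _TW1_ALPHA, a=_TW1_K, scale=_TW1_THETA)


@dataclass
class PCAResult:
    scores: np.ndarray  # n x k component scores
    eigenvalues: np.ndarray  # full descending spectrum
    eigen_pvalues: np.ndarray  # per-component Tracy-Widom p-values
    selected: np.ndarray  # component indices with p < alpha

    def covariates(self) -> np.ndarray:
        """Score columns of the selected components (n x n_selected)."""
        return self.scores[:, self.selected]


@dataclass
class GwasResult:
    snp_meta: pd.DataFrame
    beta: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    p: np.ndarray
    pve: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.snp_meta[["chrom", "pos", "snp_id"]].copy()
        df["beta"] = self.beta
        df["se"] = self.se
        df["t"] = self.tstat
        df["p"] = self.p
        if self.pve is not None:
            df["pve"] = self.pve
        return df

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class PanelSpec:
    name: str
    snp_indices: np.ndarray  # ordered by inclusion rank

    @property
    def size(self) -> int:
        return self.snp_indices.size

    def genome_order(self) -> np.ndarray:
        """Panel indices sorted by genome position (for matrix subsetting)."""
        return np.sort(self.snp_indices)


def _standardized_dosages(geno: GenotypeMatrix) -> np.ndarray:
    x = geno.dosages_float(impute_mean=True)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    return (x[:, keep] - mean[keep]) / sd[keep]


def compute_pca(geno: GenotypeMatrix, k: int = 30, alpha: float = 0.01) -> PCAResult:
    """PCA of the column-standardised dosage matrix with TW selection.

    Monomorphic columns are dropped before standardisation; missing calls
    are mean-imputed.  The full eigenvalue spectrum is retained for the
    successive Tracy-Widom tests, scores for the first ``k`` components.
    """
    n, m = geno.n_individuals, geno.n_snps
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds min(n, m)={min(n, m)}")
    z = _standardized_dosages(geno)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    eigvals = s**2 / z.shape[1]
    scores = u[:, :k] * s[:k]
    pvals = eigen_significance(eigvals, n=n, m=z.shape[1])
    selected = np.flatnonzero(pvals[:k] < alpha)
    return PCAResult(
        scores=scores, eigenvalues=eigvals, eigen_pvalues=pvals, selected=selected
    )


def eigen_significance(
    eigenvalues: np.ndarray, n: int, m: int, max_components: int = 50
) -> np.ndarray:
    """Successive Tracy-Widom p-values for leading eigenvalues.

    For the i-th eigenvalue the test is run on the spectrum with the
    previous i-1 eigenvalues removed, each time re-estimating the
    effective marker count from the remaining spectral moments.  The raw
    moment estimator overshoots the marker count by a relative factor of
    about (l + n_eff)/(l^2 - n_eff) (Wishart trace-moment corrections),
    which matters because the Tracy-Widom scale is O(n^-2/3); the estimate
    is debiased accordingly.  Only the first ``max_components`` leading
    eigenvalues are tested: deep in the spectrum the bulk-edge
    approximation no longer holds and the statistic is meaningless.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    lam = lam[lam > 1e-12]
    if lam.size < 2:
        raise ValueError("need at least two positive eigenvalues")
    pvals = np.full(lam.size, np.nan)
    n_test = min(lam.size - 2, max_components)
    for i in range(n_test):
        tail = lam[i:]
        ell = tail.size
        s1, s2 = tail.sum(), np.sum(tail**2)
        denom = (ell - 1) * s2 - s1**2
        if denom <= 0:
            break
        n_eff = (ell + 1) * s1**2 / denom
        if ell * ell > n_eff:
            n_eff = n_eff / (1.0 + (ell + n_eff) / (ell * ell - n_eff))
        lam_norm = ell * tail[0] / s1
        sq_n = np.sqrt(n_eff - 1)
        sq_l = np.sqrt(ell)
        mu = (sq_n + sq_l) ** 2 / n_eff
        sigma = (sq_n + sq_l) / n_eff * (1.0 / sq_n + 1.0 / sq_l) ** (1.0 / 3.0)
        tw = (lam_norm - mu) / sigma
        pvals[i] = float(tracy_widom_sf(tw))
    return pvals


def single_snp_assoc(
    yc: np.ndarray,
    geno: GenotypeMatrix,
    covariates: np.ndarray | None = None,
) -> GwasResult:
    """Marginal least-squares association of yc with each SNP dosage.

    Covariates (plus an intercept) are projected out of both the phenotype
    and each dosage column (Frisch-Waugh), giving the exact per-SNP OLS
    effect, SE, t and two-sided p.  Monomorphic SNPs are reported with
    beta = 0 and p = 1.
    """
    y = np.asarray(yc, dtype=np.float64)
    n = y.size
    if n != geno.n_individuals:
        raise ValueError("phenotype length does not match genotype rows")
    C = np.ones((n, 1))
    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        C = np.hstack([C, cov])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    q, _ = np.linalg.qr(C)
    resid = lambda v: v - q @ (q.T @ v)  # noqa: E731

    x = geno.dosages_float(impute_mean=True)
    y_r = resid(y)
    x_r = resid(x)

    xtx = np.einsum("ij,ij->j", x_r, x_r)
    mono = xtx <= 1e-12
    xtx_safe = np.where(mono, 1.0, xtx)
    beta = (x_r.T @ y_r) / xtx_safe
    df = n - C.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    rss = np.maximum(y_r @ y_r - beta**2 * xtx_safe, 0.0)
    se = np.sqrt(rss / df / xtx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta != 0, np.inf * np.sign(beta), 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    beta = np.where(mono, 0.0, beta)
    t = np.where(mono, 0.0, t)
    se = np.where(mono, np.nan, se)
    p = np.where(mono, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return GwasResult(snp_meta=geno.snp_meta, beta=beta, se=se, tstat=t, p=p)


def snp_pve(
    result: GwasResult, allele_freqs: np.ndarray, var_yc: float
) -> np.ndarray:
    """Per-SNP fraction of phenotypic variance: 2 f (1-f) beta^2 / var(yc)."""
    if var_yc <= 0:
        raise ValueError("var_yc must be positive")
    f = np.asarray(allele_freqs, dtype=np.float64)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    pve = 2.0 * f * (1.0 - f) * result.beta**2 / var_yc
    result.pve = np.clip(pve, 0.0, 1.0)
    return result.pve


def select_significant(result: GwasResult, alpha: float = 1e-5) -> np.ndarray:
    """SNP indices with p < alpha, sorted by ascending p."""
    hits = np.flatnonzero(result.p < alpha)
    return hits[np.argsort(result.p[hits], kind="stable")]


def build_panels(result: GwasResult, sizes: list[int]) -> list[PanelSpec]:
    """Nested SNP panels of the given sizes, ranked by ascending p-value.

    Ties are broken by genome order (input SNP order), so panels of
    increasing size are strictly nested.
    """
    sizes = list(sizes)
    m = result.p.size
    if any(s <= 0 or s > m for s in sizes):
        raise ValueError(f"panel sizes must lie in [1, {m}]")
    if sorted(sizes) != sizes:
        raise ValueError("panel sizes must be ascending")
    order = np.lexsort((np.arange(m), result.p))
    return [PanelSpec(name=f"top{s}", snp_indices=order[:s]) for s in sizes]
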