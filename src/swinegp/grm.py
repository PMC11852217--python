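"""Genomic relationship matrices, prior-information weighting, and REML.

The plain GRM is VanRaden method 1, ``G = Z Z' / (2 sum f_j (1-f_j))`` with
Z the column-centred dosage matrix.  Prior information (trait-associated
intervals from a QTL database plus genome-wide-significant loci) defines a
"weighted set" of markers which receives a target share ``omega`` of the
total marker variance, distributed proportionally to each marker's
phenotypic-variance contribution; the remaining markers share ``1-omega``
uniformly.  Heritability on the corrected scale is estimated by
single-component AI-REML with an EM fallback, worked in the eigenbasis of G
so every iteration is O(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, GRMatrix


@dataclass
class WeightSpec:
    """Which loci get up-weighted and how strongly.

    prior1_loci: BED-like intervals (chrom, start, end), e.g. QTL-database
    regions for the trait.  prior2_loci: SNP indices from the association
    scan.  The weighted set is the union of SNPs inside prior-1 intervals
    and the prior-2 set.
    """

    prior1_loci: pd.DataFrame | None = None
    prior2_loci: np.ndarray | None = None
    per_snp_pve: np.ndarray | None = None
    weight_fraction: float = 0.7

    def validate(self) -> None:
        if not 0.0 < self.weight_fraction < 1.0:
            raise ValueError("weight_fraction must lie in (0, 1)")

    def weighted_set(self, snp_meta: pd.DataFrame) -> np.ndarray:
        mask = np.zeros(len(snp_meta), dtype=bool)
        if self.prior1_loci is not None and len(self.prior1_loci):
            chrom = snp_meta["chrom"].astype(str).to_numpy()
            pos = snp_meta["pos"].to_numpy()
            for _, row in self.prior1_loci.iterrows():
                mask |= (chrom == str(row["chrom"])) & (pos >= row["start"]) & (
                    pos <= row["end"]
                )
        if self.prior2_loci is not None:
            mask[np.asarray(self.prior2_loci, dtype=int)] = True
        return np.flatnonzero(mask)


def _freqs_and_centered(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    x = geno.dosages_float(impute_mean=True)
    f = x.mean(axis=0) / 2.0
    return f, x - 2.0 * f


def vanraden_grm(geno: GenotypeMatrix) -> GRMatrix:
    """VanRaden method-1 GRM; monomorphic SNPs are excluded with a warning."""
    f, z = _freqs_and_centered(geno)
    poly = (f > 0) & (f < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from the GRM",
            stacklevel=2,
        )
        f, z = f[poly], z[:, poly]
    if f.size == 0:
        raise ValueError("no polymorphic SNPs available")
    denom = 2.0 * np.sum(f * (1.0 - f))
    values = (z @ z.T) / denom
    values = (values + values.T) / 2.0
    return GRMatrix(values=values, sample_ids=list(geno.sample_ids), weights_used=None)


def assign_weights(
    spec: WeightSpec, snp_meta: pd.DataFrame, allele_freqs: np.ndarray
) -> np.ndarray:
    """Per-SNP weights giving the weighted set an ``omega`` variance share.

    With h_j = 2 f_j (1-f_j) and T = sum h_j, weights on the weighted set S
    are proportional to per-SNP PVE and rescaled so sum_{S} w_j h_j =
    omega * T; the complement shares (1-omega) * T uniformly.  With S = all
    SNPs and flat PVE this reduces to uniform weights.
    """
    spec.validate()
    if spec.per_snp_pve is None:
        raise ValueError("per_snp_pve is required to assign weights")
    f = np.asarray(allele_freqs, dtype=np.float64)
    h = 2.0 * f * (1.0 - f)
    total = h.sum()
    sel = spec.weighted_set(snp_meta)
    if sel.size == 0:
        raise ValueError("empty weighted set with weight_fraction > 0")
    pve = np.asarray(spec.per_snp_pve, dtype=np.float64)
    omega = spec.weight_fraction

    w = np.zeros(len(snp_meta))
    sel_mass = np.sum(pve[sel] * h[sel])
    if sel_mass <= 0:
        raise ValueError("weighted set has zero PVE mass")
    w[sel] = pve[sel] * (omega * total / sel_mass)
    rest = np.setdiff1d(np.arange(len(snp_meta)), sel)
    if rest.size:
        w[rest] = (1.0 - omega) * total / h[rest].sum()
    return w


def weighted_grm(geno: GenotypeMatrix, weights: np.ndarray) -> GRMatrix:
    """Weighted VanRaden GRM, ``Z D Z' / sum_j w_j 2 f_j (1-f_j)``.

    Uniform weights reproduce :func:`vanraden_grm`; the normalised form is
    invariant to rescaling all weights by a constant.
    """
    w = np.asarray(weights, dtype=np.float64)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("weights must not all be zero")
    f, z = _freqs_and_centered(geno)
    keep = (f > 0) & (f < 1) & (w > 0)
    f, z, w = f[keep], z[:, keep], w[keep]
    denom = np.sum(w * 2.0 * f * (1.0 - f))
    values = (z * w) @ z.T / denom
    values = (values + values.T) / 2.0
    return GRMatrix(
        values=values, sample_ids=list(geno.sample_ids), weights_used=np.asarray(weights)
    )


@dataclass
class RemlResult:
    h2: float
    se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    n_iter: int
    converged: bool
    trajectory: list[float] = field(default_factory=list)


def reml_h2(
    G: GRMatrix,
    yc: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RemlResult:
    """Single-component AI-REML for yc = mu + g + e, g ~ N(0, G sigma_g2).

    Average-information updates with an EM fallback whenever an AI step
    leaves the parameter space or decreases the restricted likelihood.
    Variance components are floored at 1e-8; the SE of h2 comes from the
    inverse AI matrix by the delta method.
    """
    y = np.asarray(yc, dtype=np.float64)
    n = y.size
    if n != G.n:
        raise ValueError("phenotype length does not match GRM order")

    lam, U = np.linalg.eigh(G.values)
    lam = np.maximum(lam, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def core(theta: np.ndarray):
        sg, se_ = theta
        d = sg * lam + se_
        di = 1.0 / d
        xdx = np.sum(xt**2 * di)
        xdy = np.sum(xt * yt * di)
        # P v in rotated coordinates
        Pv = lambda v: v * di - xt * di * (np.sum(xt * v * di) / xdx)  # noqa: E731
        py = Pv(yt)
        ll = -0.5 * (np.sum(np.log(d)) + np.log(xdx) + y @ (U @ py))
        return d, di, xdx, Pv, py, ll

    var_y = np.var(y, ddof=1)
    theta = np.array([var_y / 2.0, var_y / 2.0])
    floor = 1e-8 * var_y
    traj: list[float] = []
    ll_old = -np.inf
    converged = False
    ai = np.eye(2)
    for it in range(1, max_iter + 1):
        d, di, xdx, Pv, py, ll = core(theta)
        traj.append(float(ll))

        a_mats = (lam, np.ones(n))  # rotated G and I are diagonal
        tr_pa = []
        ypapy = []
        for a in a_mats:
            tr = np.sum(a * di) - np.sum(a * xt**2 * di**2) / xdx
            tr_pa.append(tr)
            ypapy.append(np.sum(py * a * py) * 1.0)
        grad = np.array([-0.5 * (tr_pa[k] - float(np.array(ypapy[k]))) for k in range(2)])

        papy = [Pv(a * py) for a in a_mats]
        ai = 0.5 * np.array(
            [[np.sum((a_mats[k] * py) * papy[l]) for l in range(2)] for k in range(2)]
        )
        ai = (ai + ai.T) / 2.0

        step_ok = False
        try:
            delta = np.linalg.solve(ai, grad)
            for halving in range(4):  # clamped AI step with step-halving
                cand = np.maximum(theta + delta / 2**halving, floor)
                _, _, _, _, _, ll_cand = core(cand)
                if np.isfinite(ll_cand) and ll_cand >= ll - 1e-10:
                    theta_new, step_ok = cand, True
                    break
        except np.linalg.LinAlgError:
            pass
        if not step_ok:  # EM-REML fallback, monotone in likelihood
            theta_new = np.array(
                [
                    max(theta[k] + theta[k] ** 2 / n * (ypapy[k] - tr_pa[k]), floor)
                    for k in range(2)
                ]
            )

        if abs(ll - ll_old) < tol and it > 1:
            converged = True
            theta = theta_new
            break
        ll_old = ll
        theta = np.maximum(theta_new, floor)
    if not converged:
        # AI/EM can crawl when the optimum sits on a boundary (h2 -> 0 or 1);
        # rescue with a 1-D profile-likelihood search over h2, profiling out
        # the overall scale analytically.
        from scipy.optimize import minimize_scalar

        def neg_profile_ll(h: float) -> float:
            w = h * lam + (1.0 - h)
            wi = 1.0 / w
            xdx = np.sum(xt**2 * wi)
            py = yt * wi - xt * wi * (np.sum(xt * yt * wi) / xdx)
            quad = yt @ py
            if quad <= 0 or xdx <= 0:
                return np.inf
            s_hat = quad / (n - 1)
            return 0.5 * (
                (n - 1) * np.log(s_hat) + np.sum(np.log(w)) + np.log(xdx) + (n - 1)
            )

        opt = minimize_scalar(
            neg_profile_ll, bounds=(1e-8, 1.0 - 1e-8), method="bounded",
            options={"xatol": 1e-9},
        )
        if not np.isfinite(opt.fun):
            raise RuntimeError(
                f"REML did not converge in {max_iter} iterations; "
                f"trajectory={traj[-5:]}"
            )
        h = float(opt.x)
        w = h * lam + (1.0 - h)
        wi = 1.0 / w
        xdx = np.sum(xt**2 * wi)
        py = yt * wi - xt * wi * (np.sum(xt * yt * wi) / xdx)
        s_hat = (yt @ py) / (n - 1)
        theta = np.array([max(h * s_hat, floor), max((1.0 - h) * s_hat, floor)])
        d, di, xdx, Pv, py, ll = core(theta)
        traj.append(float(ll))
        papy = [Pv(a * py) for a in (lam, np.ones(n))]
        ai = 0.5 * np.array(
            [
                [np.sum(((lam, np.ones(n))[k] * py) * papy[l]) for l in range(2)]
                for k in range(2)
            ]
        )
        converged = True

    sg, se_ = theta
    h2 = float(sg / (sg + se_))
    try:
        ai_inv = np.linalg.inv(ai)
        gvec = np.array([se_, -sg]) / (sg + se_) ** 2
        se_h2 = float(np.sqrt(max(gvec @ ai_inv @ gvec, 0.0)))
    except np.linalg.LinAlgError:  # pragma: no cover
        se_h2 = float("nan")
    return RemlResult(
        h2=h2,
        se=se_h2,
        sigma_g2=float(sg),
        sigma_e2=float(se_),
        loglik=float(traj[-1]),
        n_iter=len(traj),
        converged=converged,
        trajectory=traj,
    )
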