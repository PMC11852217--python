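"""Phenotype correction: fixed-effect adjustment, outlier removal, scaling.

Raw reproduction records (litter weight, total number born, number born
alive) are confounded with management factors, so each trait is first
corrected with the linear model ``y = Xb + e`` where X carries the fixed
effects (farrowing year, month, total litter size, ...).  The residuals e
are screened for aberrant records and standardised; the resulting unitless
vector ``yc`` is what every prediction model downstream consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import PhenotypeTable


@dataclass
class CorrectedPhenotype:
    sample_ids: list[str]
    yc: np.ndarray
    n_removed: int
    removal_rule: str


def build_design_matrix(
    tab: PhenotypeTable, add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: dummy-coded categoricals + numerics.

    The first level of each categorical factor is absorbed into the
    intercept (reference coding) so X is full rank for nested-free designs.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        blocks.append(np.ones((len(tab.data), 1)))
        names.append("intercept")
    for col in tab.categorical_covariates:
        dummies = pd.get_dummies(tab.data[col].astype("category"), drop_first=True)
        blocks.append(dummies.to_numpy(dtype=np.float64))
        names.extend(f"{col}={lvl}" for lvl in dummies.columns)
    for col in tab.numeric_covariates:
        vals = tab.data[col].to_numpy(dtype=np.float64)
        blocks.append(vals[:, None])
        names.append(col)
    X = np.hstack(blocks) if blocks else np.empty((len(tab.data), 0))
    return X, names


def fit_correction_model(tab: PhenotypeTable, trait: str) -> np.ndarray:
    """Least-squares residuals of one trait on the fixed-effect design.

    Returns e = y - X b_hat with b_hat the OLS solution; e is orthogonal to
    the column space of X.  Raises if X is rank deficient, naming a column
    involved in the collinearity.
    """
    if trait not in tab.trait_cols:
        raise KeyError(f"unknown trait {trait!r}; table has {tab.trait_cols}")
    y = tab.data[trait].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(y)):
        raise ValueError("trait column contains non-finite values")
    X, names = build_design_matrix(tab)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column whose removal restores full column rank
        for j in range(X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                raise ValueError(
                    f"design matrix is rank deficient; column {names[j]!r} is collinear"
                )
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def remove_aberrant(
    e: np.ndarray, rule: float = 3.0, iterate: bool = False
) -> tuple[np.ndarray, np.ndarray, int]:
    """Drop records with |e - mean(e)| > rule * sd(e).

    Applied once by default; with ``iterate=True`` the screen is repeated on
    the surviving records until no record exceeds the threshold.  Returns
    (filtered residuals, boolean keep-mask over the input, number removed).
    """
    if rule <= 0:
        raise ValueError("rule must be positive (SD units)")
    e = np.asarray(e, dtype=np.float64)
    keep = np.ones(e.size, dtype=bool)
    while True:
        cur = e[keep]
        if cur.size == 0:
            raise ValueError("outlier rule removed every record")
        sd = np.std(cur, ddof=1) if cur.size > 1 else 0.0
        if sd == 0:
            break
        out = np.abs(e - np.mean(cur)) > rule * sd
        new_keep = keep & ~out
        if new_keep.sum() == keep.sum() or not iterate:
            keep = new_keep
            break
        keep = new_keep
    if keep.sum() == 0:
        raise ValueError("outlier rule removed every record")
    return e[keep], keep, int(e.size - keep.sum())


def standardize(e: np.ndarray) -> np.ndarray:
    """Zero-mean unit-variance scaling with the n-1 sample SD."""
    e = np.asarray(e, dtype=np.float64)
    sd = np.std(e, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (e - np.mean(e)) / sd


def correct_trait(
    tab: PhenotypeTable,
    trait: str,
    outlier_rule: float = 3.0,
    iterate_outliers: bool = False,
) -> CorrectedPhenotype:
    """Full correction pipeline: fit Xb, drop aberrant records, standardise."""
    e = fit_correction_model(tab, trait)
    _, keep, n_removed = remove_aberrant(e, rule=outlier_rule, iterate=iterate_outliers)
    yc = standardize(e[keep])
    ids = [s for s, k in zip(tab.sample_ids, keep) if k]
    return CorrectedPhenotype(
        sample_ids=ids,
        yc=yc,
        n_removed=n_removed,
        removal_rule=f"|residual| > {outlier_rule} SD"
        + (" (iterated)" if iterate_outliers else ""),
    )


def write_corrected(cp: CorrectedPhenotype, path: str) -> None:
    pd.DataFrame({"sample_id": cp.sample_ids, "yc": cp.yc}).to_csv(path, sep="\t", index=False)


def read_corrected(path: str) -> CorrectedPhenotype:
    df = pd.read_csv(path, sep="\t")
    return CorrectedPhenotype(
        sample_ids=df["sample_id"].astype(str).tolist(),
        yc=df["yc"].to_numpy(dtype=np.float64),
        n_removed=0,
        removal_rule="loaded from file",
    )
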