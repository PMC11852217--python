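"""Evaluation harness: accuracy, cross-validation, Bayesian tuning, ANOVA.

Prediction accuracy is the Pearson correlation between predicted and
observed corrected phenotypes.  Model comparison uses seeded fivefold
cross-validation on the training population plus a single held-out
independent test, with hyperparameters tuned by a Gaussian-process
expected-improvement search.  A one-way fixed-effects ANOVA compares the
trait distributions themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def accuracy(ypred: np.ndarray, ytrue: np.ndarray) -> float:
    """Pearson correlation r between predictions and observations."""
    ypred = np.asarray(ypred, dtype=np.float64)
    ytrue = np.asarray(ytrue, dtype=np.float64)
    if ypred.size != ytrue.size or ypred.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(ypred) == 0 or np.std(ytrue) == 0:
        warnings.warn("constant vector: correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(ypred, ytrue)[0, 1])


@dataclass
class CVReport:
    method: str
    fold_r: list[float]
    seed: int
    panel_size: int | None = None
    weighted: bool = False

    @property
    def mean_r(self) -> float:
        vals = [v for v in self.fold_r if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd_r(self) -> float:
        vals = [v for v in self.fold_r if np.isfinite(v)]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded partition of range(n) into k near-equal disjoint folds."""
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and n >= k")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def kfold_cv(
    y: np.ndarray,
    fit_predict,
    k: int = 5,
    seed: int = 0,
    method: str = "",
    panel_size: int | None = None,
    weighted: bool = False,
) -> CVReport:
    """k-fold CV of a (train_idx, test_idx) -> predictions callable.

    Each fold's accuracy is the Pearson r on the held-out individuals; the
    report keeps per-fold values so mean and SD always recompute exactly.
    """
    y = np.asarray(y, dtype=np.float64)
    folds = make_folds(len(y), k, seed)
    fold_r = []
    all_idx = np.arange(len(y))
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        preds = np.asarray(fit_predict(train_idx, test_idx), dtype=np.float64)
        fold_r.append(accuracy(preds, y[test_idx]))
    return CVReport(
        method=method, fold_r=fold_r, seed=seed, panel_size=panel_size, weighted=weighted
    )


# ---------------------------------------------------------- Bayesian tuning


@dataclass
class TuneResult:
    space: dict
    evaluated: list[tuple[dict, float]]
    best_params: dict
    best_value: float
    n_iterations: int


def _encode(params: dict, space: dict) -> np.ndarray:
    cols = []
    for name, spec in space.items():
        kind = spec[0]
        v = params[name]
        if kind == "float":
            lo, hi = spec[1], spec[2]
            log = len(spec) > 3 and spec[3] == "log"
            if log:
                cols.append((np.log(v) - np.log(lo)) / (np.log(hi) - np.log(lo)))
            else:
                cols.append((v - lo) / (hi - lo))
        elif kind == "int":
            lo, hi = spec[1], spec[2]
            cols.append((v - lo) / max(hi - lo, 1))
        elif kind == "cat":
            onehot = [1.0 if v == c else 0.0 for c in spec[1]]
            cols.extend(onehot)
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return np.array(cols)


def _sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "float":
            lo, hi = spec[1], spec[2]
            if len(spec) > 3 and spec[3] == "log":
                out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                out[name] = float(rng.uniform(lo, hi))
        elif kind == "int":
            out[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "cat":
            out[name] = spec[1][rng.integers(0, len(spec[1]))]
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return out


def _matern52(d: np.ndarray) -> np.ndarray:
    a = np.sqrt(5.0) * d
    return (1.0 + a + a**2 / 3.0) * np.exp(-a)


def bayes_opt(
    objective,
    space: dict,
    n_iter: int = 300,
    seed: int = 0,
    n_candidates: int = 512,
    lengthscale: float = 0.25,
) -> TuneResult:
    """Maximise a black-box objective with a GP surrogate and EI.

    ``space`` maps names to ("float", lo, hi[, "log"]), ("int", lo, hi) or
    ("cat", [choices]).  Inputs are normalised to the unit cube (one-of-k
    for categoricals) under a Matern-5/2 kernel.  Objectives returning
    non-finite values are recorded as failures and never become the best
    point.  Deterministic given the seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    evaluated: list[tuple[dict, float]] = []
    Xs: list[np.ndarray] = []
    ys: list[float] = []

    n_init = min(max(5, 2 * len(space)), n_iter)
    for it in range(n_iter):
        if it < n_init or len(ys) < 2:
            params = _sample_params(space, rng)
        else:
            X = np.vstack(Xs)
            yv = np.asarray(ys)
            y_mean, y_sd = yv.mean(), max(yv.std(), 1e-12)
            yn = (yv - y_mean) / y_sd
            d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1) / lengthscale
            K = _matern52(d) + 1e-6 * np.eye(len(yn))
            try:
                L = np.linalg.cholesky(K)
                alpha = np.linalg.solve(L.T, np.linalg.solve(L, yn))
            except np.linalg.LinAlgError:
                params = _sample_params(space, rng)
                alpha = None
            if alpha is not None:
                cands = [_sample_params(space, rng) for _ in range(n_candidates)]
                Xc = np.vstack([_encode(c, space) for c in cands])
                dc = (
                    np.linalg.norm(Xc[:, None, :] - X[None, :, :], axis=-1)
                    / lengthscale
                )
                Kc = _matern52(dc)
                mu = Kc @ alpha
                v = np.linalg.solve(L, Kc.T)
                var = np.maximum(1.0 - np.einsum("ij,ij->j", v, v), 1e-12)
                sd = np.sqrt(var)
                best = yn.max()
                z = (mu - best) / sd
                ei = sd * (z * stats.norm.cdf(z) + stats.norm.pdf(z))
                params = cands[int(np.argmax(ei))]
        val = objective(**params)
        val = float(val) if np.isfinite(val) else float("nan")
        evaluated.append((params, val))
        if np.isfinite(val):
            Xs.append(_encode(params, space))
            ys.append(val)

    if not ys:
        raise RuntimeError("every objective evaluation failed")
    finite = [(p, v) for p, v in evaluated if np.isfinite(v)]
    best_params, best_value = max(finite, key=lambda t: t[1])
    return TuneResult(
        space=space,
        evaluated=evaluated,
        best_params=best_params,
        best_value=float(best_value),
        n_iterations=n_iter,
    )


# ------------------------------------------------- independent test, ANOVA


def independent_test(
    predict,
    y_holdout: np.ndarray,
    train_ids: list[str] | None = None,
    holdout_ids: list[str] | None = None,
    allow_overlap: bool = False,
) -> float:
    """Single accuracy on a reserved holdout with a leakage guard.

    ``predict`` is a zero-argument callable returning predictions for the
    holdout individuals from a model whose hyperparameters were frozen
    after cross-validation (no refitting here).
    """
    if train_ids is not None and holdout_ids is not None and not allow_overlap:
        overlap = set(train_ids) & set(holdout_ids)
        if overlap:
            raise ValueError(f"train/holdout id overlap (leakage): {sorted(overlap)[:5]}")
    preds = np.asarray(predict(), dtype=np.float64)
    return accuracy(preds, y_holdout)


def consistency(cv_series: np.ndarray, indep_series: np.ndarray) -> float:
    """Pearson r between CV and independent-test accuracies across panels."""
    return accuracy(np.asarray(cv_series), np.asarray(indep_series))


@dataclass
class AnovaTable:
    ss_between: float
    df_between: int
    ss_within: float
    df_within: int
    alpha: float = 0.05
    ms_between: float = field(init=False)
    ms_within: float = field(init=False)
    f: float = field(init=False)
    p: float = field(init=False)
    f_crit: float = field(init=False)

    def __post_init__(self) -> None:
        if self.df_between < 1 or self.df_within < 1:
            raise ValueError("degrees of freedom must be positive")
        if self.ss_within <= 0:
            raise ValueError("zero within-group variance")
        self.ms_between = self.ss_between / self.df_between
        self.ms_within = self.ss_within / self.df_within
        self.f = self.ms_between / self.ms_within
        self.p = float(stats.f.sf(self.f, self.df_between, self.df_within))
        self.f_crit = float(stats.f.isf(self.alpha, self.df_between, self.df_within))

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def df_total(self) -> int:
        return self.df_between + self.df_within


def anova_across_traits(trait_vectors: list[np.ndarray]) -> AnovaTable:
    """One-way fixed-effects ANOVA across trait samples."""
    groups = [np.asarray(g, dtype=np.float64) for g in trait_vectors]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    return AnovaTable(
        ss_between=float(ss_between),
        df_between=len(groups) - 1,
        ss_within=float(ss_within),
        df_within=int(all_vals.size - len(groups)),
    )
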