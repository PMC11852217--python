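"""Machine-learning regressors on genomic-relationship features.

Each individual is represented by its row of the genomic relationship
matrix restricted to the training columns - a relationship profile to the
reference population - which sidesteps the p >> n marker dimensionality.
On these features the module provides kernel ridge regression (closed
form), CART-style regression trees, bagged random forests, gradient-boosted
trees with an optional gradient-based one-side sampling (GOSS) variant, and
AdaBoost.R2 with the weighted-median combination rule.  Everything is
seed-reproducible and serialisable; no third-party learner is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GRMatrix

# ---------------------------------------------------------------- features


@dataclass
class FeatureView:
    """Relationship-profile feature matrix: G[query, train] rows."""

    matrix: np.ndarray
    row_ids: list[str]
    train_ids: list[str]


def make_features(
    G_joint: GRMatrix, train_ids: list[str], query_ids: list[str]
) -> FeatureView:
    """Feature vector of individual i = (G[i, j]) for j in train_ids."""
    rows = G_joint.index_of(query_ids)
    cols = G_joint.index_of(train_ids)
    return FeatureView(
        matrix=G_joint.values[np.ix_(rows, cols)],
        row_ids=list(query_ids),
        train_ids=list(train_ids),
    )


# --------------------------------------------------------------------- KRR


@dataclass
class KernelModel:
    kind: str  # "linear" (kernel matrix supplied) or "rbf"
    lam: float
    dual_coef: np.ndarray
    gamma: float | None = None
    train_features: np.ndarray | None = None  # rbf only


def rbf_kernel(Xa: np.ndarray, Xb: np.ndarray, gamma: float) -> np.ndarray:
    sq = (
        np.sum(Xa**2, axis=1)[:, None]
        + np.sum(Xb**2, axis=1)[None, :]
        - 2.0 * Xa @ Xb.T
    )
    return np.exp(-gamma * np.maximum(sq, 0.0))


def fit_krr(K_train: np.ndarray, y: np.ndarray, lam: float) -> KernelModel:
    """Dual ridge solve ``alpha = (K + lam I)^-1 y`` on a precomputed kernel."""
    K = np.asarray(K_train, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if lam <= 0:
        raise ValueError("regularization lam must be positive")
    if K.shape[0] != K.shape[1] or K.shape[0] != y.size:
        raise ValueError("kernel must be square and match y")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kernel must be symmetric")
    w = np.linalg.eigvalsh(K)
    if w[0] < -1e-6 * max(1.0, w[-1]):
        raise ValueError(f"kernel is not PSD within tolerance (min eig {w[0]:.3g})")
    dual = np.linalg.solve(K + lam * np.eye(K.shape[0]), y)
    return KernelModel(kind="linear", lam=lam, dual_coef=dual)


def fit_krr_rbf(X: np.ndarray, y: np.ndarray, lam: float, gamma: float) -> KernelModel:
    K = rbf_kernel(X, X, gamma)
    model = fit_krr(K, y, lam)
    return KernelModel(
        kind="rbf", lam=lam, dual_coef=model.dual_coef, gamma=gamma, train_features=X
    )


def predict_krr(model: KernelModel, k_rows: np.ndarray) -> np.ndarray:
    """Prediction ``k' (K + lam I)^-1 y`` for query kernel rows (or raw
    features in rbf mode)."""
    k_rows = np.atleast_2d(np.asarray(k_rows, dtype=np.float64))
    if model.kind == "rbf":
        k_rows = rbf_kernel(k_rows, model.train_features, model.gamma)
    if k_rows.shape[1] != model.dual_coef.size:
        raise ValueError("kernel rows do not match the training set size")
    return k_rows @ model.dual_coef


# ------------------------------------------------------------------- trees


@dataclass
class EnsembleConfig:
    n_estimators: int = 100
    max_depth: int = 5
    min_samples_leaf: int = 5
    learning_rate: float = 0.1
    subsample: float = 1.0  # bagging fraction (RF bootstrap is with replacement)
    feature_fraction: float = 1.0  # per-split feature subsampling
    goss_top: float | None = None  # GOSS a: keep-fraction by |gradient|
    goss_rest: float | None = None  # GOSS b: random fraction of the remainder
    loss: str = "linear"  # AdaBoost.R2 loss: linear | square | exponential
    histogram_bins: int | None = None  # None = exact midpoint splits
    seed: int = 0

    def validate(self) -> None:
        if self.n_estimators < 0:
            raise ValueError("n_estimators must be >= 0")
        if not 0.0 < self.learning_rate <= 1.0:
            raise ValueError("learning_rate must lie in (0, 1]")
        for name in ("subsample", "feature_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.loss not in ("linear", "square", "exponential"):
            raise ValueError("loss must be linear, square or exponential")


@dataclass
class TreeNode:
    value: float
    feature: int = -1
    threshold: float = np.nan
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value}
        return {
            "value": self.value,
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class RegressionTree:
    root: TreeNode
    bin_edges: list[np.ndarray] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.empty(X.shape[0])
        stack = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf or idx.size == 0:
                out[idx] = node.value
                continue
            go_left = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
        return out


def _best_split_exact(X, y, w, idx, features, min_leaf):
    best = (-np.inf, -1, np.nan)
    yw = y[idx] * w[idx]
    tot_w, tot_s = w[idx].sum(), yw.sum()
    base = tot_s**2 / tot_w
    for f in features:
        order = idx[np.argsort(X[idx, f], kind="stable")]
        xv = X[order, f]
        cw = np.cumsum(w[order])[:-1]
        cs = np.cumsum(y[order] * w[order])[:-1]
        cnt = np.arange(1, idx.size)
        valid = (xv[:-1] < xv[1:]) & (cnt >= min_leaf) & (idx.size - cnt >= min_leaf)
        if not valid.any():
            continue
        gain = cs**2 / cw + (tot_s - cs) ** 2 / (tot_w - cw) - base
        gain = np.where(valid, gain, -np.inf)
        b = int(np.argmax(gain))
        if gain[b] > best[0] + 1e-12:
            best = (float(gain[b]), f, float((xv[b] + xv[b + 1]) / 2.0))
    return best


def _best_split_hist(Xb, edges, y, w, idx, features, min_leaf, n_bins):
    p = Xb.shape[1]
    flat = (Xb[idx] + np.arange(p, dtype=np.int64) * n_bins).ravel()
    cnt = np.bincount(flat, minlength=p * n_bins).reshape(p, n_bins)
    sw = np.bincount(flat, weights=np.repeat(w[idx], p), minlength=p * n_bins).reshape(
        p, n_bins
    )
    sy = np.bincount(
        flat, weights=np.repeat(y[idx] * w[idx], p), minlength=p * n_bins
    ).reshape(p, n_bins)
    lc = np.cumsum(cnt, axis=1)[:, :-1]
    lw = np.cumsum(sw, axis=1)[:, :-1]
    ls = np.cumsum(sy, axis=1)[:, :-1]
    tw, ts, tc = sw.sum(axis=1, keepdims=True), sy.sum(axis=1, keepdims=True), idx.size
    base = ts**2 / tw
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = ls**2 / lw + (ts - ls) ** 2 / (tw - lw) - base
    valid = (lc >= min_leaf) & (tc - lc >= min_leaf) & (lw > 0) & (tw - lw > 0)
    mask = np.zeros(p, dtype=bool)
    mask[features] = True
    gain = np.where(valid & mask[:, None], gain, -np.inf)
    f, b = np.unravel_index(int(np.argmax(gain)), gain.shape)
    if not np.isfinite(gain[f, b]) or gain[f, b] <= 1e-12:
        return (-np.inf, -1, np.nan)
    return (float(gain[f, b]), int(f), float(edges[f][b]))


def fit_tree(
    features: np.ndarray,
    y: np.ndarray,
    cfg: EnsembleConfig | None = None,
    sample_weight: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    _binned: tuple[np.ndarray, list[np.ndarray]] | None = None,
) -> RegressionTree:
    """CART regression tree with greedy variance-reduction splits.

    Exact midpoint thresholds by default; with ``cfg.histogram_bins`` set,
    features are pre-binned and split candidates are bin boundaries (much
    faster on dense GRM features).  Deterministic given seed and feature
    order; a constant target yields a single leaf.
    """
    cfg = cfg or EnsembleConfig()
    cfg.validate()
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if n < 2 * cfg.min_samples_leaf and n > 1:
        pass  # allowed: tree degenerates to its root leaf
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
    rng = rng or np.random.default_rng(cfg.seed)

    edges = None
    Xb = None
    if cfg.histogram_bins is not None:
        if _binned is not None:
            Xb, edges = _binned
        else:
            Xb, edges = bin_features(X, cfg.histogram_bins)
        n_bins = max(len(e) for e in edges) + 1

    n_feat = max(1, int(round(cfg.feature_fraction * p)))

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node_val = float(np.average(y[idx], weights=w[idx]))
        if depth >= cfg.max_depth or idx.size < 2 * cfg.min_samples_leaf:
            return TreeNode(value=node_val)
        if np.all(y[idx] == y[idx[0]]):
            return TreeNode(value=node_val)
        feats = (
            np.arange(p)
            if n_feat == p
            else np.sort(rng.choice(p, size=n_feat, replace=False))
        )
        if Xb is not None:
            gain, f, thr = _best_split_hist(
                Xb, edges, y, w, idx, feats, cfg.min_samples_leaf, n_bins
            )
        else:
            gain, f, thr = _best_split_exact(X, y, w, idx, feats, cfg.min_samples_leaf)
        if f < 0:
            return TreeNode(value=node_val)
        go_left = X[idx, f] <= thr
        left, right = idx[go_left], idx[~go_left]
        if left.size == 0 or right.size == 0:
            return TreeNode(value=node_val)
        node = TreeNode(value=node_val, feature=int(f), threshold=float(thr))
        node.left = grow(left, depth + 1)
        node.right = grow(right, depth + 1)
        return node

    root = grow(np.arange(n), 0)
    return RegressionTree(root=root, bin_edges=edges)


def bin_features(X: np.ndarray, n_bins: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Quantile-bin each feature; returns (codes, per-feature upper edges)."""
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = []
    codes = np.empty(X.shape, dtype=np.int64)
    for f in range(X.shape[1]):
        e = np.unique(np.quantile(X[:, f], qs))
        edges.append(e)
        codes[:, f] = np.searchsorted(e, X[:, f], side="left")
    return codes, edges


# --------------------------------------------------------------- ensembles


@dataclass
class ForestModel:
    trees: list[RegressionTree]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.mean([t.predict(X) for t in self.trees], axis=0)


@dataclass
class GbdtModel:
    base: float
    trees: list[RegressionTree]
    learning_rate: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        out = np.full(X.shape[0], self.base)
        for t in self.trees:
            out += self.learning_rate * t.predict(X)
        return out

    def staged_train_mse(self, X: np.ndarray, y: np.ndarray) -> list[float]:
        out = np.full(len(y), self.base)
        mses = [float(np.mean((y - out) ** 2))]
        for t in self.trees:
            out += self.learning_rate * t.predict(X)
            mses.append(float(np.mean((y - out) ** 2)))
        return mses


@dataclass
class AdaboostModel:
    learners: list[RegressionTree]
    log_inv_eps: np.ndarray  # log(1/eps_t) per learner
    stopped_early: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        preds = np.vstack([t.predict(X) for t in self.learners])  # T x n
        return weighted_median(preds, self.log_inv_eps)


def weighted_median(preds: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Infimum-form weighted median per column of a T x n prediction stack.

    Returns, per sample, the smallest prediction y such that the learners
    predicting <= y carry at least half the total weight.
    """
    order = np.argsort(preds, axis=0, kind="stable")
    sorted_preds = np.take_along_axis(preds, order, axis=0)
    sorted_w = weights[order]
    csum = np.cumsum(sorted_w, axis=0)
    half = 0.5 * weights.sum()
    first = np.argmax(csum >= half - 1e-12, axis=0)
    return sorted_preds[first, np.arange(preds.shape[1])]


def fit_rf(
    features: np.ndarray, y: np.ndarray, cfg: EnsembleConfig | None = None
) -> ForestModel:
    """Bootstrap-bagged trees with per-split feature subsampling.

    With ``n_estimators=1``, ``subsample=1`` (interpreted as "no
    bootstrap") and ``feature_fraction=1`` this reduces exactly to a single
    :func:`fit_tree`.
    """
    cfg = cfg or EnsembleConfig()
    cfg.validate()
    if cfg.n_estimators < 1:
        raise ValueError("random forest needs at least one tree")
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    binned = bin_features(X, cfg.histogram_bins) if cfg.histogram_bins else None
    trees = []
    for _ in range(cfg.n_estimators):
        if cfg.subsample < 1.0 or cfg.n_estimators > 1:
            idx = rng.integers(0, len(y), size=int(round(cfg.subsample * len(y))))
            w = np.bincount(idx, minlength=len(y)).astype(float)
            sub = np.flatnonzero(w)
            Xs, ys, ws = X[sub], y[sub], w[sub]
            sub_binned = (binned[0][sub], binned[1]) if binned else None
        else:
            Xs, ys, ws, sub_binned = X, y, None, binned
        trees.append(
            fit_tree(Xs, ys, cfg, sample_weight=ws, rng=rng, _binned=sub_binned)
        )
    return ForestModel(trees=trees)


def fit_gbdt(
    features: np.ndarray, y: np.ndarray, cfg: EnsembleConfig | None = None
) -> GbdtModel:
    """Gradient boosting on squared loss, optional GOSS instance sampling.

    Stage m fits a tree to the current residuals and is added with
    shrinkage ``learning_rate``.  With GOSS enabled (``goss_top=a``,
    ``goss_rest=b``) each stage keeps the top a-fraction of samples by
    |residual| plus a random b-fraction of the remainder upweighted by
    (1-a)/b; ``a=1`` keeps every sample and is bitwise identical to plain
    GBDT.
    """
    cfg = cfg or EnsembleConfig()
    cfg.validate()
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    binned = bin_features(X, cfg.histogram_bins) if cfg.histogram_bins else None
    base = float(np.mean(y))
    F = np.full(n, base)
    trees: list[RegressionTree] = []
    for _ in range(cfg.n_estimators):
        resid = y - F
        if cfg.goss_top is not None and cfg.goss_top < 1.0:
            b = cfg.goss_rest if cfg.goss_rest is not None else 0.1
            n_top = int(np.ceil(cfg.goss_top * n))
            order = np.argsort(-np.abs(resid), kind="stable")
            top = order[:n_top]
            rest = order[n_top:]
            n_rest = int(np.ceil(b * rest.size))
            picked = rng.choice(rest, size=n_rest, replace=False) if n_rest else rest[:0]
            idx = np.sort(np.concatenate([top, picked]))
            w = np.ones(n)
            w[picked] = (1.0 - cfg.goss_top) / b
            tree = fit_tree(
                X[idx],
                resid[idx],
                cfg,
                sample_weight=w[idx],
                rng=rng,
                _binned=(binned[0][idx], binned[1]) if binned else None,
            )
        else:
            tree = fit_tree(X, resid, cfg, rng=rng, _binned=binned)
        F += cfg.learning_rate * tree.predict(X)
        trees.append(tree)
    return GbdtModel(base=base, trees=trees, learning_rate=cfg.learning_rate)


def _r2_losses(err: np.ndarray, loss: str, scale: float = 1.0) -> np.ndarray:
    m = err.max()
    if m <= 1e-12 * (1.0 + scale):  # numerically perfect fit
        return np.zeros_like(err)
    L = err / m
    if loss == "square":
        L = L**2
    elif loss == "exponential":
        L = 1.0 - np.exp(-L)
    return L


def fit_adaboost_r2(
    features: np.ndarray, y: np.ndarray, cfg: EnsembleConfig | None = None
) -> AdaboostModel:
    """Drucker's AdaBoost.R2 with trees as weak learners.

    Per round: fit on a weight-resampled bootstrap, normalise absolute
    errors to [0,1] by the chosen loss, form the average loss Lbar and the
    error rate eps = Lbar/(1-Lbar), update sample weights by
    eps^(1-L_i), and stop once Lbar >= 0.5.  The committee predicts the
    weighted median with per-learner weights log(1/eps).
    """
    cfg = cfg or EnsembleConfig()
    cfg.validate()
    X = np.atleast_2d(np.asarray(features, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    D = np.full(n, 1.0 / n)
    learners: list[RegressionTree] = []
    lw: list[float] = []
    stopped = False
    for t in range(cfg.n_estimators):
        idx = rng.choice(n, size=n, replace=True, p=D)
        tree = fit_tree(X[idx], y[idx], cfg, rng=rng)
        pred = tree.predict(X)
        L = _r2_losses(np.abs(pred - y), cfg.loss, scale=float(np.abs(y).max()))
        lbar = float(np.sum(D * L))
        if lbar >= 0.5:
            if not learners:
                import warnings

                warnings.warn(
                    "first weak learner has average loss >= 0.5; "
                    "falling back to a single learner",
                    stacklevel=2,
                )
                learners.append(tree)
                lw.append(1.0)
            stopped = True
            break
        eps = lbar / (1.0 - lbar) if lbar > 0 else 1e-12
        learners.append(tree)
        lw.append(float(np.log(1.0 / eps)))
        D = D * eps ** (1.0 - L)
        D = D / D.sum()
    return AdaboostModel(
        learners=learners, log_inv_eps=np.asarray(lw), stopped_early=stopped
    )
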