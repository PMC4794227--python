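"""Least-squares gradient-boosted regression trees, written from scratch.

The scoring function is the additive model

    f(x) = F0 + sum_{m=1..N_tree} eps * T_m(x),

where each T_m is a depth-limited regression tree grown greedily on the
residuals of all previous trees, eps is the shrinkage (learning rate), and
F0 = 0.  Regression targets are 1 for disease-associated and 0 for neutral
variants, so scores are interpretable against a probability-like cutoff
(0.45 by default).  Defaults follow the published configuration: eps = 0.005,
N_tree = 2000, maximal depth 8; these are empirical, not optimized.

Determinism: no row or feature subsampling; split candidates are midpoints
between consecutive distinct sorted feature values; ties between equal-gain
splits break toward the lowest feature index, then the lowest threshold.
Two fits on identical inputs therefore produce bit-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DEFAULT_SHRINKAGE = 0.005
DEFAULT_N_TREES = 2000
DEFAULT_MAX_DEPTH = 8
DEFAULT_MIN_LEAF = 5
DEFAULT_CUTOFF = 0.45

# Tree nodes are plain dicts so models serialize to JSON verbatim:
#   leaf:     {"value": v}
#   internal: {"feature": j, "threshold": t, "left": node, "right": node}


def _best_split(X: np.ndarray, r: np.ndarray, min_leaf: int):
    """Exhaustive vectorized search for the squared-error-optimal split.

    Returns (feature, threshold, gain) where gain is the SSE reduction, or
    None when no valid split improves on the parent node.
    """
    n, d = X.shape
    if n < 2 * min_leaf:
        return None
    order = np.argsort(X, axis=0, kind="stable")
    Xs = np.take_along_axis(X, order, axis=0)
    rs = r[order]
    csum = np.cumsum(rs, axis=0)
    total = csum[-1]
    n_left = np.arange(1, n, dtype=float)[:, None]
    n_right = n - n_left
    s_left = csum[:-1]
    s_right = total[None, :] - s_left
    score = s_left * s_left / n_left + s_right * s_right / n_right
    valid = Xs[1:] > Xs[:-1]
    if min_leaf > 1:
        k = np.arange(1, n)
        valid &= ((k >= min_leaf) & (n - k >= min_leaf))[:, None]
    score = np.where(valid, score, -np.inf)
    # argmax picks the first maximum: lowest threshold within a feature,
    # then lowest feature index across features.
    best_row = np.argmax(score, axis=0)
    per_feature = score[best_row, np.arange(d)]
    j = int(np.argmax(per_feature))
    if not np.isfinite(per_feature[j]):
        return None
    gain = float(per_feature[j] - total[j] * total[j] / n)
    if gain <= 0.0:
        return None
    i = int(best_row[j])
    threshold = float((Xs[i, j] + Xs[i + 1, j]) / 2.0)
    return j, threshold, gain


def _grow(X: np.ndarray, r: np.ndarray, depth: int, max_depth: int, min_leaf: int) -> dict:
    if depth >= max_depth or len(r) < 2 or np.all(r == r[0]):
        return {"value": float(r.mean())}
    split = _best_split(X, r, min_leaf)
    if split is None:
        return {"value": float(r.mean())}
    j, threshold, _gain = split
    go_left = X[:, j] <= threshold
    if not go_left.any() or go_left.all():  # degenerate midpoint rounding
        return {"value": float(r.mean())}
    return {
        "feature": j,
        "threshold": threshold,
        "left": _grow(X[go_left], r[go_left], depth + 1, max_depth, min_leaf),
        "right": _grow(X[~go_left], r[~go_left], depth + 1, max_depth, min_leaf),
    }


@dataclass
class RegressionTree:
    root: dict

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        self._route(self.root, X, np.arange(X.shape[0]), out)
        return out

    def _route(self, node: dict, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if "value" in node:
            out[idx] = node["value"]
            return
        go_left = X[idx, node["feature"]] <= node["threshold"]
        self._route(node["left"], X, idx[go_left], out)
        self._route(node["right"], X, idx[~go_left], out)

    def n_nodes(self) -> int:
        def count(node: dict) -> int:
            if "value" in node:
                return 1
            return 1 + count(node["left"]) + count(node["right"])

        return count(self.root)

    def depth(self) -> int:
        def d(node: dict) -> int:
            if "value" in node:
                return 0
            return 1 + max(d(node["left"]), d(node["right"]))

        return d(self.root)


@dataclass
class BoostedModel:
    trees: list[RegressionTree] = field(default_factory=list)
    shrinkage: float = DEFAULT_SHRINKAGE
    base_score: float = 0.0
    n_features: Optional[int] = None
    feature_config: str = "ENTPRISE"
    train_mse: Optional[list[float]] = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def fit_tree(
    X: np.ndarray,
    r: np.ndarray,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
) -> RegressionTree:
    """Grow one least-squares regression tree on residuals r.

    Greedy top-down; each split maximizes the squared-error reduction over
    all (feature, midpoint-threshold) candidates; leaf values are residual
    means.  A constant residual vector yields a single leaf.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = np.asarray(r, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot fit a tree on an empty sample")
    if X.shape[0] != r.shape[0]:
        raise ValueError("X and residuals disagree in sample count")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite residual")
    return RegressionTree(root=_grow(X, r, 0, max_depth, min_leaf))


def fit(
    X: np.ndarray,
    y: np.ndarray,
    shrinkage: float = DEFAULT_SHRINKAGE,
    n_trees: int = DEFAULT_N_TREES,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_leaf: int = DEFAULT_MIN_LEAF,
    feature_config: str = "ENTPRISE",
    track_mse: bool = False,
) -> BoostedModel:
    """Boost n_trees residual trees on 0/1 labels with shrinkage eps.

    F0 = 0; at stage m the tree is fit to r = y - f_{m-1}(X) and
    f_m = f_{m-1} + eps * T_m.  Training MSE is non-increasing in m for any
    eps in (0, 2).  Fully deterministic.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary 0/1")
    f = np.zeros(X.shape[0])
    trees: list[RegressionTree] = []
    mse_path: list[float] = []
    for _ in range(n_trees):
        r = y - f
        tree = fit_tree(X, r, max_depth=max_depth, min_leaf=min_leaf)
        trees.append(tree)
        f = f + shrinkage * tree.predict(X)
        if track_mse:
            mse_path.append(float(np.mean((y - f) ** 2)))
    return BoostedModel(
        trees=trees,
        shrinkage=shrinkage,
        base_score=0.0,
        n_features=X.shape[1],
        feature_config=feature_config,
        train_mse=mse_path if track_mse else None,
    )


def predict_score(model: BoostedModel, X: np.ndarray) -> np.ndarray | float:
    """f(x) = F0 + sum_m eps * T_m(x); routing is left iff feature <= threshold."""
    arr = np.asarray(X, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if model.n_features is not None and arr.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {arr.shape[1]} does not match model "
            f"({model.n_features} features, config {model.feature_config})"
        )
    score = np.full(arr.shape[0], model.base_score, dtype=float)
    for tree in model.trees:
        score += model.shrinkage * tree.predict(arr)
    return float(score[0]) if single else score


def classify(score, cutoff: float = DEFAULT_CUTOFF):
    """"disease" iff score > cutoff (strict); vectorizes over arrays."""
    arr = np.asarray(score, dtype=float)
    labels = np.where(arr > cutoff, "disease", "neutral")
    return str(labels[()]) if arr.ndim == 0 else labels
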