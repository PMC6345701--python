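"""Second-order gradient-boosted regression trees, written from scratch.

Each boosting round fits a regression tree to the first and second
derivatives (g_i, h_i) of the logistic loss at the current margins.  With
G and H the per-leaf sums of g and h, the optimal leaf weight is

    w* = -G / (H + λ)

and the gain of splitting a leaf into (L, R), under an L2 leaf penalty λ
and a per-leaf penalty γ, is

    gain = ½ [ G_L²/(H_L+λ) + G_R²/(H_R+λ) − G_P²/(H_P+λ) ] − γ .

Trees are grown greedily one level at a time with exact split enumeration:
every feature, every midpoint between consecutive distinct sorted values.
Ties are broken toward the lowest feature index, then the lowest
threshold.  Multi-label classification uses the binary relevance strategy:
one independent boosted ensemble per location.

No subsampling, no histogram approximation — exact greedy enumeration is
affordable at the feature dimensions produced by the CNN extractor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cnn import bce_loss, sigmoid


# ---------------------------------------------------------------------------
# Primitives

@dataclass
class GradStats:
    """Accumulated derivative sums over a set of data points."""

    g: float  # sum of first derivatives (gradient)
    h: float  # sum of second derivatives (hessian)
    count: int | None = None  # number of points, when tracked


def logistic_grad_hess(y: float, margin: float):
    """Derivatives of the pointwise logistic loss at the given margin:
    ``g = σ(margin) − y``, ``h = σ(margin)(1 − σ(margin))``."""
    p = float(sigmoid(np.asarray(float(margin))))
    return p - y, p * (1.0 - p)


def leaf_weight(stats: GradStats, reg_lambda: float) -> float:
    """Optimal weight of a leaf with fixed membership: ``−G/(H+λ)``."""
    denom = stats.h + reg_lambda
    if denom <= 0.0:
        raise ValueError("degenerate leaf: H + lambda must be positive")
    return -stats.g / denom


def split_gain(
    parent: GradStats,
    left: GradStats,
    reg_lambda: float,
    gamma: float,
) -> float:
    """Objective reduction from splitting ``parent`` into ``left`` and its
    complement, minus the per-leaf penalty γ."""
    right = GradStats(
        parent.g - left.g,
        parent.h - left.h,
        None if parent.count is None or left.count is None
        else parent.count - left.count,
    )
    if right.count == 0 or (
        right.count is None and left.g == parent.g and left.h == parent.h
    ):
        raise ValueError("right child is empty: left must be a proper subset")
    if min(parent.h, left.h, right.h) < 0:
        raise ValueError("negative hessian sum")

    def score(s: GradStats) -> float:
        return s.g * s.g / (s.h + reg_lambda)

    return 0.5 * (score(left) + score(right) - score(parent)) - gamma


# ---------------------------------------------------------------------------
# Trees

@dataclass
class GBTParams:
    """Hyperparameters for one boosted ensemble."""

    n_rounds: int = 100
    learning_rate: float = 0.3
    max_depth: int = 3
    reg_lambda: float = 1.0
    gamma: float = 0.0
    min_child_hessian: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.reg_lambda < 0 or self.gamma < 0 or self.max_depth < 1:
            raise ValueError("need lambda >= 0, gamma >= 0, max_depth >= 1")


class DecisionTree:
    """A regression tree: internal nodes (feature, threshold), leaf weights.

    A point goes left when ``x[feature] < threshold``; thresholds are
    midpoints between consecutive distinct training values, so no training
    point ever sits on a threshold.
    """

    def __init__(self, root: dict):
        self.root = root

    @property
    def n_leaves(self) -> int:
        def count(node):
            if "leaf" in node:
                return 1
            return count(node["left"]) + count(node["right"])

        return count(self.root)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])

        def fill(node, idx):
            if "leaf" in node:
                out[idx] = node["leaf"]
                return
            go_left = X[idx, node["feature"]] < node["threshold"]
            fill(node["left"], idx[go_left])
            fill(node["right"], idx[~go_left])

        fill(self.root, np.arange(X.shape[0]))
        return out

    def to_dict(self) -> dict:
        return self.root

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        return cls(d)


def _best_split(X, g, h, idx, reg_lambda, gamma, min_child_hessian):
    """Exact greedy split search over one node's points.

    Returns (gain, feature, threshold) or None.  Ties broken toward the
    lowest feature index, then the lowest threshold.

    A prefix-sum scan screens the candidates; the near-best ones are then
    re-scored with direct sums over the actual partitions, so that ranking
    and tie-breaking do not depend on floating-point accumulation order.
    """
    Gp, Hp = g[idx].sum(), h[idx].sum()
    parent_term = Gp * Gp / (Hp + reg_lambda)
    best = None
    for f in range(X.shape[1]):
        xs = X[idx, f]
        order = np.argsort(xs, kind="stable")
        xs_s = xs[order]
        cg = np.cumsum(g[idx][order])[:-1]
        ch = np.cumsum(h[idx][order])[:-1]
        lo, hi = xs_s[:-1], xs_s[1:]
        boundary = lo < hi
        if not boundary.any():
            continue
        thr = (lo + hi) / 2.0
        GL, HL = cg, ch
        GR, HR = Gp - GL, Hp - HL
        gains = (
            0.5
            * (GL**2 / (HL + reg_lambda) + GR**2 / (HR + reg_lambda)
               - parent_term)
            - gamma
        )
        ok = (
            boundary
            & (HL >= min_child_hessian)
            & (HR >= min_child_hessian)
            & (thr > lo)
            & (thr < hi)
        )
        gains = np.where(ok, gains, -np.inf)
        top = gains.max()
        if not np.isfinite(top):
            continue
        # re-score candidates within the screening band with direct sums
        band = gains >= top - 1e-6 * max(1.0, abs(top))
        for i in np.flatnonzero(band):
            t = float(thr[i])
            left = xs < t
            gl, hl = g[idx[left]].sum(), h[idx[left]].sum()
            gr, hr = g[idx[~left]].sum(), h[idx[~left]].sum()
            if hl < min_child_hessian or hr < min_child_hessian:
                continue
            gain = (
                0.5
                * (gl * gl / (hl + reg_lambda) + gr * gr / (hr + reg_lambda)
                   - parent_term)
                - gamma
            )
            if best is None or gain > best[0]:
                best = (float(gain), f, t)
    return best


def grow_tree(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, params: GBTParams
) -> DecisionTree:
    """Grow one tree greedily, level by level, to ``max_depth``.

    A node stays a leaf when its best gain is ≤ 0 or a child's hessian sum
    would fall below ``min_child_hessian``; leaves get the optimal weight
    ``−G/(H+λ)``.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("empty input")
    if not (np.isfinite(g).all() and np.isfinite(h).all()):
        raise ValueError("non-finite gradient or hessian")
    params.validate()

    def leaf(idx):
        stats = GradStats(g[idx].sum(), h[idx].sum(), len(idx))
        return {"leaf": leaf_weight(stats, params.reg_lambda)}

    def build(idx, depth):
        if depth >= params.max_depth or len(idx) < 2:
            return leaf(idx)
        found = _best_split(
            X, g, h, idx, params.reg_lambda, params.gamma,
            params.min_child_hessian,
        )
        if found is None or found[0] <= 0.0:
            return leaf(idx)
        _, f, thr = found
        go_left = X[idx, f] < thr
        return {
            "feature": f,
            "threshold": thr,
            "left": build(idx[go_left], depth + 1),
            "right": build(idx[~go_left], depth + 1),
        }

    return DecisionTree(build(np.arange(X.shape[0]), 0))


def tree_objective(
    tree: DecisionTree,
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    reg_lambda: float,
    gamma: float,
) -> float:
    """Evaluate ``−½ Σ_j G_j²/(H_j+λ) + γT`` for a tree on data (X, g, h)."""
    X = np.asarray(X, dtype=float)
    total = 0.0
    n_leaves = 0

    def walk(node, idx):
        nonlocal total, n_leaves
        if "leaf" in node:
            G, H = g[idx].sum(), h[idx].sum()
            total += -0.5 * G * G / (H + reg_lambda)
            n_leaves += 1
            return
        go_left = X[idx, node["feature"]] < node["threshold"]
        walk(node["left"], idx[go_left])
        walk(node["right"], idx[~go_left])

    walk(tree.root, np.arange(X.shape[0]))
    return total + gamma * n_leaves


# ---------------------------------------------------------------------------
# Boosted ensembles

class GradientBoostingBinaryClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier: additive ensemble of second-order trees.

    The initial prediction is the training log-odds (clipped away from 0
    and 1); each round adds a tree fit to the logistic loss derivatives at
    the current margins, scaled by the learning rate (shrinkage).
    """

    def __init__(
        self,
        n_rounds: int = 100,
        learning_rate: float = 0.3,
        max_depth: int = 3,
        reg_lambda: float = 1.0,
        gamma: float = 0.0,
        min_child_hessian: float = 1e-3,
        base_margin: float | None = None,
        seed: int = 0,
    ):
        self.n_rounds = n_rounds
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.min_child_hessian = min_child_hessian
        self.base_margin = base_margin
        self.seed = seed

    def _params(self) -> GBTParams:
        return GBTParams(
            n_rounds=self.n_rounds,
            learning_rate=self.learning_rate,
            max_depth=self.max_depth,
            reg_lambda=self.reg_lambda,
            gamma=self.gamma,
            min_child_hessian=self.min_child_hessian,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on n")
        params = self._params()
        params.validate()
        n = y.shape[0]
        if self.base_margin is None:
            p_bar = float(np.clip(y.mean(), 1.0 / (n + 2), (n + 1.0) / (n + 2)))
            self.base_margin_ = float(np.log(p_bar / (1.0 - p_bar)))
        else:
            self.base_margin_ = float(self.base_margin)
        margins = np.full(n, self.base_margin_)
        self.trees_: list[DecisionTree] = []
        self.train_loss_: list[float] = []
        for _ in range(self.n_rounds):
            p = sigmoid(margins)
            g = p - y
            h = p * (1.0 - p)
            tree = grow_tree(X, g, h, params)
            self.trees_.append(tree)
            margins = margins + self.learning_rate * tree.predict(X)
            self.train_loss_.append(bce_loss(y[:, None], margins[:, None]))
        return self

    def predict_margin(self, X) -> np.ndarray:
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        margin = np.full(X.shape[0], self.base_margin_)
        for tree in self.trees_:
            margin += self.learning_rate * tree.predict(X)
        return margin

    def predict_proba_pos(self, X) -> np.ndarray:
        return sigmoid(self.predict_margin(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.predict_proba_pos(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba_pos(X) >= 0.5).astype(int)

    # serialization helpers (JSON-able structure)
    def to_dict(self) -> dict:
        check_is_fitted(self, "trees_")
        return {
            "base_margin": self.base_margin_,
            "learning_rate": self.learning_rate,
            "trees": [t.to_dict() for t in self.trees_],
        }


class BinaryRelevanceClassifier(ClassifierMixin, BaseEstimator):
    """One independent boosted ensemble per location (binary relevance)."""

    def __init__(
        self,
        n_rounds: int = 100,
        learning_rate: float = 0.3,
        max_depth: int = 3,
        reg_lambda: float = 1.0,
        gamma: float = 0.0,
        min_child_hessian: float = 1e-3,
        threshold: float = 0.5,
        seed: int = 0,
    ):
        self.n_rounds = n_rounds
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.min_child_hessian = min_child_hessian
        self.threshold = threshold
        self.seed = seed

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim != 2 or Y.shape[1] < 1:
            raise ValueError("Y must be n×n_labels with >= 1 label column")
        self.estimators_: list[GradientBoostingBinaryClassifier] = []
        for j in range(Y.shape[1]):
            est = GradientBoostingBinaryClassifier(
                n_rounds=self.n_rounds,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                reg_lambda=self.reg_lambda,
                gamma=self.gamma,
                min_child_hessian=self.min_child_hessian,
                seed=(self.seed * 9973 + j) % (2**31),
            )
            self.estimators_.append(est.fit(X, Y[:, j]))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        return np.column_stack(
            [est.predict_proba_pos(X) for est in self.estimators_]
        )

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.threshold).astype(int)


# ---------------------------------------------------------------------------
# Functional wrappers

def fit_binary_gbt(X, y, params: GBTParams) -> GradientBoostingBinaryClassifier:
    return GradientBoostingBinaryClassifier(
        n_rounds=params.n_rounds,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        reg_lambda=params.reg_lambda,
        gamma=params.gamma,
        min_child_hessian=params.min_child_hessian,
        seed=params.seed,
    ).fit(X, y)


def fit_binary_relevance(X, Y, params: GBTParams) -> BinaryRelevanceClassifier:
    return BinaryRelevanceClassifier(
        n_rounds=params.n_rounds,
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        reg_lambda=params.reg_lambda,
        gamma=params.gamma,
        min_child_hessian=params.min_child_hessian,
        seed=params.seed,
    ).fit(X, Y)


def predict_margin(ensemble: GradientBoostingBinaryClassifier, X):
    return ensemble.predict_margin(X)
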