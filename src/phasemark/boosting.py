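"""Boosting classifiers used to compare biomarker gene sets.

Two ensembles of weak tree learners, both binary:

* :class:`AdaBoostStumps` — discrete AdaBoost over depth-1 decision
  stumps.  Each round fits a stump on the weighted sample, receives the
  vote a_i = 1/2 ln((1 - err)/err), and up-weights misclassified samples;
  the ensemble score is sign(sum_i a_i h_i(x)).

* :class:`GradientBoostedTrees` — gradient boosting with logistic loss
  and the regularizer r = gamma * M + 1/2 lambda * sum_j w_j^2 over the M
  leaf weights of each tree.  Trees are grown best-first by exact greedy
  split search; each leaf takes the penalized Newton step
  w = -G / (H + lambda), where G and H are the sums of the loss gradients
  and Hessians of the samples in the leaf, and a split is kept only when
  its gain exceeds the per-leaf penalty gamma.

Both models expose ``fit(X, y)`` with y in {0, 1} and
``predict_proba(X)`` returning the positive-class probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"need both classes 0 and 1, got classes {classes}")
    return y


# ---------------------------------------------------------------------------
# AdaBoost with decision stumps


@dataclass
class DecisionStump:
    """Axis-aligned threshold rule: predict ``polarity`` where x_j > thr."""

    feature: int
    threshold: float
    polarity: int  # +1: predict +1 above threshold; -1: predict +1 below

    def predict(self, X: np.ndarray) -> np.ndarray:
        above = X[:, self.feature] > self.threshold
        return np.where(above, self.polarity, -self.polarity)


def fit_stump(X: np.ndarray, y_pm: np.ndarray, w: np.ndarray) -> DecisionStump:
    """Exhaustive weighted-error minimization over features x thresholds.

    Thresholds are midpoints between adjacent distinct sorted values plus
    the two outer cuts; ties in error resolve to the first candidate in
    scan order (feature, cut position, polarity +1 before -1).
    """
    n, p = X.shape
    best = (np.inf, 0, 0.0, 1)
    total_pos = float(w[y_pm == 1].sum())
    total_neg = float(w[y_pm == -1].sum())
    for j in range(p):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        ys = y_pm[order]
        cum_pos = np.cumsum(np.where(ys == 1, ws, 0.0))
        cum_neg = np.cumsum(np.where(ys == -1, ws, 0.0))
        # cut after position k (0..n-1): x <= xs[k] predicted below-side
        valid = np.flatnonzero(xs[:-1] < xs[1:])
        cuts = np.concatenate([valid, [n - 1]])  # include "all below" cut
        thr = np.where(cuts < n - 1, (xs[cuts] + xs[np.minimum(cuts + 1, n - 1)]) / 2.0, xs[-1])
        err_plus = cum_pos[cuts] + (total_neg - cum_neg[cuts])  # polarity +1
        err_minus = (total_pos + total_neg) - err_plus  # polarity -1
        for errs, pol in ((err_plus, 1), (err_minus, -1)):
            k = int(np.argmin(errs))
            if errs[k] < best[0] - 1e-15:
                best = (float(errs[k]), j, float(thr[k]), pol)
    return DecisionStump(best[1], best[2], best[3])


@dataclass
class AdaBoostStumps:
    """Discrete AdaBoost over decision stumps."""

    n_rounds: int = 100
    weak_learners: list[DecisionStump] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "AdaBoostStumps":
        X = np.asarray(X, dtype=float)
        y = _check_binary(y)
        y_pm = np.where(y == 1, 1, -1)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.weak_learners, self.weights = [], []
        for _ in range(self.n_rounds):
            stump = fit_stump(X, y_pm, w)
            h = stump.predict(X)
            err = float(w[h != y_pm].sum())
            if err >= 0.5:
                break  # weak learner no better than chance: stop, discard
            eps = np.finfo(float).tiny
            alpha = 0.5 * np.log((1.0 - err + eps) / (err + eps))
            self.weak_learners.append(stump)
            self.weights.append(float(alpha))
            if err == 0.0:
                break  # perfectly separated: further rounds are idle
            w = w * np.exp(-alpha * y_pm * h)
            w /= w.sum()
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        score = np.zeros(X.shape[0])
        for a, stump in zip(self.weights, self.weak_learners):
            score += a * stump.predict(X)
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # logistic link on the margin; monotone in the ensemble score
        return 1.0 / (1.0 + np.exp(-2.0 * self.decision_function(X)))


# ---------------------------------------------------------------------------
# Gradient-boosted trees with penalized Newton leaf weights


@dataclass
class GradBoostParams:
    n_rounds: int = 100
    learning_rate: float = 0.3
    max_leaves: int = 8
    leaf_penalty: float = 0.0  # gamma: per-leaf cost
    l2_penalty: float = 1.0  # lambda: L2 on leaf weights
    loss: str = "logistic"

    def __post_init__(self) -> None:
        if self.l2_penalty < 0 or self.leaf_penalty < 0:
            raise ValueError("penalties must be non-negative")
        if self.max_leaves < 1:
            raise ValueError("max_leaves must be >= 1")
        if self.loss != "logistic":
            raise ValueError("only logistic loss is supported")


def leaf_weight(G: float, H: float, l2_penalty: float) -> float:
    """Penalized Newton step for a leaf with gradient/Hessian sums G, H."""
    return -G / (H + l2_penalty)


@dataclass
class _TreeNode:
    feature: int = -1
    threshold: float = 0.0
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None
    value: float = 0.0  # leaf weight when feature == -1


def _best_split(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, idx: np.ndarray, lam: float, gamma: float
) -> tuple[float, int, float] | None:
    """Exact greedy split search on the samples in ``idx``.

    Returns (gain, feature, threshold) for the best gain-positive split,
    or None.  Gain is the structure-score improvement minus gamma.
    """
    G, H = float(g[idx].sum()), float(h[idx].sum())
    parent = G * G / (H + lam)
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        xs_order = idx[np.argsort(X[idx, j], kind="stable")]
        xs = X[xs_order, j]
        gl = np.cumsum(g[xs_order])
        hl = np.cumsum(h[xs_order])
        valid = np.flatnonzero(xs[:-1] < xs[1:])
        if valid.size == 0:
            continue
        GL, HL = gl[valid], hl[valid]
        GR, HR = G - GL, H - HL
        gain = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - parent) - gamma
        k = int(np.argmax(gain))
        if gain[k] > 1e-12 and (best is None or gain[k] > best[0]):
            best = (float(gain[k]), j, float((xs[valid[k]] + xs[valid[k] + 1]) / 2.0))
    return best


def _grow_tree(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, params: GradBoostParams
) -> _TreeNode:
    lam, gamma = params.l2_penalty, params.leaf_penalty
    root = _TreeNode()
    all_idx = np.arange(X.shape[0])
    leaves: list[tuple[_TreeNode, np.ndarray]] = [(root, all_idx)]
    candidates = {id(root): _best_split(X, g, h, all_idx, lam, gamma)}
    while len(leaves) < params.max_leaves:
        grown = [(node, idx) for node, idx in leaves if candidates[id(node)] is not None]
        if not grown:
            break
        node, idx = max(grown, key=lambda t: candidates[id(t[0])][0])  # type: ignore[index]
        gain, j, thr = candidates[id(node)]  # type: ignore[misc]
        mask = X[idx, j] <= thr
        node.feature, node.threshold = j, thr
        node.left, node.right = _TreeNode(), _TreeNode()
        li, ri = idx[mask], idx[~mask]
        leaves.remove((node, idx))
        leaves.extend([(node.left, li), (node.right, ri)])
        candidates[id(node.left)] = _best_split(X, g, h, li, lam, gamma)
        candidates[id(node.right)] = _best_split(X, g, h, ri, lam, gamma)
    for node, idx in leaves:
        node.value = leaf_weight(float(g[idx].sum()), float(h[idx].sum()), lam)
    return root


def _predict_tree(node: _TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if nd.feature < 0:
            out[idx] = nd.value
            continue
        mask = X[idx, nd.feature] <= nd.threshold
        stack.append((nd.left, idx[mask]))  # type: ignore[arg-type]
        stack.append((nd.right, idx[~mask]))  # type: ignore[arg-type]
    return out


@dataclass
class GradientBoostedTrees:
    params: GradBoostParams = field(default_factory=GradBoostParams)
    trees: list[_TreeNode] = field(default_factory=list)
    base_score: float = 0.0  # log-odds of the training base rate

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostedTrees":
        X = np.asarray(X, dtype=float)
        y = _check_binary(y).astype(float)
        rate = float(y.mean())
        self.base_score = float(np.log(rate / (1.0 - rate)))
        self.trees = []
        F = np.full(X.shape[0], self.base_score)
        for _ in range(self.params.n_rounds):
            p = 1.0 / (1.0 + np.exp(-F))
            g = p - y
            h = np.maximum(p * (1.0 - p), 1e-16)
            tree = _grow_tree(X, g, h, self.params)
            self.trees.append(tree)
            F = F + self.params.learning_rate * _predict_tree(tree, X)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        F = np.full(X.shape[0], self.base_score)
        for tree in self.trees:
            F = F + self.params.learning_rate * _predict_tree(tree, X)
        return F

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


def train_adaboost(X: np.ndarray, y: np.ndarray, n_rounds: int = 100) -> AdaBoostStumps:
    return AdaBoostStumps(n_rounds=n_rounds).fit(X, y)


def train_gradient_boosting(
    X: np.ndarray, y: np.ndarray, params: GradBoostParams | None = None
) -> GradientBoostedTrees:
    return GradientBoostedTrees(params=params or GradBoostParams()).fit(X, y)
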