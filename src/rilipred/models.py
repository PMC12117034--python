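"""The three RILI classifiers, as scikit-learn-compatible estimators.

All three are authored here from first principles with the fixed
hyperparameters reported for the clinical cohort; scikit-learn supplies
only estimator plumbing (``BaseEstimator`` / ``ClassifierMixin`` and input
validation), never the learning algorithm.

* :class:`GiniTreeClassifier` — a binary CART-style tree grown *best-first*
  under a tree-wide split budget (default 100): at every step the split
  with the largest weighted Gini impurity decrease anywhere on the frontier
  is taken. Thresholds are midpoints between consecutive distinct feature
  values; ties break to the lowest feature index, then lowest threshold.
  Zero-gain splits of impure nodes are permitted (parity patterns such as
  XOR have no positive-gain first split yet are perfectly separable).

* :class:`DistanceWeightedKNNClassifier` — k-nearest neighbours (default
  k = 84, Euclidean) with squared-inverse-distance vote weights 1/d^2.
  Zero-distance neighbours dominate: if a query coincides with training
  points, the majority label among those points wins outright. This is
  what makes resubstitution accuracy exactly 100% on training sets with
  pairwise-distinct rows. Distance ties at the k-boundary include all tied
  neighbours.

* :class:`RandomFeatureKernelLogistic` — a Gaussian-kernel classifier via a
  random cosine feature map z(x) = sqrt(2/D) cos(Wx/sigma + b) (W standard
  normal, b uniform on [0, 2*pi)), with an L2-regularised logistic head
  (default D = 115, lambda = 0.55035) fitted by damped full-batch Newton
  iteration; the intercept is unpenalised.

Features are standardised (train mean / sample SD) inside each estimator
unless disabled; constant columns get scale 1 with a warning. Models
serialise to a documented JSON schema via :func:`save_model` /
:func:`load_model`.
"""

from __future__ import annotations

import heapq
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "StandardizationParams",
    "standardize_fit",
    "standardize_apply",
    "GiniTreeClassifier",
    "DistanceWeightedKNNClassifier",
    "RandomFeatureKernelLogistic",
    "fit_tree",
    "predict_tree",
    "fit_knn",
    "predict_knn",
    "fit_kernel_logistic",
    "predict_kernel",
    "gini_impurity",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
]


# ---------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class StandardizationParams:
    center: np.ndarray
    scale: np.ndarray


def standardize_fit(X: np.ndarray) -> StandardizationParams:
    """Column means and sample SDs; constant columns get scale 1 + warning."""
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1) if X.shape[0] >= 2 else np.zeros(X.shape[1])
    constant = scale == 0
    if constant.any():
        warnings.warn(
            f"constant feature column(s) {np.flatnonzero(constant).tolist()}: "
            "scale set to 1",
            stacklevel=2,
        )
        scale = np.where(constant, 1.0, scale)
    return StandardizationParams(center=center, scale=scale)


def standardize_apply(params: StandardizationParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.center) / params.scale


def _validate_fit(est, X, y):
    X, y = check_X_y(X, y)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values; missing data is rejected")
    classes = np.unique(y)
    if classes.size > 2:
        raise ValueError(f"binary classification only, got classes {classes.tolist()}")
    est.classes_ = classes
    est.n_features_in_ = X.shape[1]
    y01 = np.searchsorted(classes, y)
    return X, y01


def gini_impurity(counts) -> float:
    """Gini diversity index 1 - sum p_c^2 of a class-count vector."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


# ---------------------------------------------------------------------------
# Gini decision tree


@dataclass
class _TreeNode:
    counts: np.ndarray  # class counts of training samples reaching the node
    feature: int | None = None
    threshold: float | None = None
    left: "_TreeNode | None" = None
    right: "_TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def proba(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else np.full_like(self.counts, 0.5)


def _best_split(X, y01, idx, n_total):
    """Best (gain, feature, threshold) for one node, or None.

    Gain is the weighted Gini decrease (node_n*g - nL*gL - nR*gR)/n_total.
    Zero gain is admissible when the node is impure; ties prefer the lowest
    feature index, then the lowest threshold.
    """
    y_node = y01[idx]
    n = idx.size
    c1 = int(y_node.sum())
    parent = n * gini_impurity([n - c1, c1])
    if c1 == 0 or c1 == n:
        return None
    best = None
    for j in range(X.shape[1]):
        v = X[idx, j]
        order = np.argsort(v, kind="stable")
        vs, ys = v[order], y_node[order]
        boundary = np.flatnonzero(vs[:-1] < vs[1:])
        if boundary.size == 0:
            continue
        cum1 = np.cumsum(ys)
        n_left = boundary + 1
        c1_left = cum1[boundary].astype(float)
        c0_left = n_left - c1_left
        c1_right = c1 - c1_left
        c0_right = (n - n_left) - c1_right
        with np.errstate(invalid="ignore"):
            g_left = n_left - (c0_left**2 + c1_left**2) / n_left
            g_right = (n - n_left) - (c0_right**2 + c1_right**2) / (n - n_left)
        gains = (parent - g_left - g_right) / n_total
        k = int(np.argmax(gains))  # first max => lowest threshold
        if gains[k] >= -1e-12 and (best is None or gains[k] > best[0] + 1e-15):
            thr = (vs[boundary[k]] + vs[boundary[k] + 1]) / 2.0
            best = (max(float(gains[k]), 0.0), j, thr)
    return best


class GiniTreeClassifier(ClassifierMixin, BaseEstimator):
    """Binary CART tree, best-first growth under a global split budget.

    Parameters
    ----------
    max_splits : int, default 100
        Tree-wide cap on the number of internal nodes ("Fine Tree"
        granularity); growth stops earlier if all leaves are pure.

    Attributes
    ----------
    tree_ : _TreeNode
        Root of the fitted tree.
    n_splits_ : int
        Number of internal nodes actually created (<= max_splits).
    """

    def __init__(self, max_splits: int = 100):
        self.max_splits = max_splits

    def fit(self, X, y):
        if self.max_splits < 0:
            raise ValueError("max_splits must be >= 0")
        X, y01 = _validate_fit(self, X, y)
        n_classes = self.classes_.size
        n_total = X.shape[0]

        def counts_of(idx):
            c = np.zeros(max(n_classes, 2))
            for k in range(n_classes):
                c[k] = int((y01[idx] == k).sum())
            return c

        root_idx = np.arange(n_total)
        root = _TreeNode(counts=counts_of(root_idx))
        heap: list[tuple] = []
        order = 0
        if n_classes == 2:
            cand = _best_split(X, y01, root_idx, n_total)
            if cand is not None:
                heapq.heappush(heap, (-cand[0], order, cand[1], cand[2], root, root_idx))
                order += 1
        n_splits = 0
        while heap and n_splits < self.max_splits:
            neg_gain, _, j, thr, node, idx = heapq.heappop(heap)
            go_left = X[idx, j] <= thr
            left_idx, right_idx = idx[go_left], idx[~go_left]
            node.feature, node.threshold = int(j), float(thr)
            node.left = _TreeNode(counts=counts_of(left_idx))
            node.right = _TreeNode(counts=counts_of(right_idx))
            n_splits += 1
            for child, child_idx in ((node.left, left_idx), (node.right, right_idx)):
                cand = _best_split(X, y01, child_idx, n_total)
                if cand is not None:
                    heapq.heappush(
                        heap, (-cand[0], order, cand[1], cand[2], child, child_idx)
                    )
                    order += 1
        self.tree_ = root
        self.n_splits_ = n_splits
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "tree_")
        X = check_array(X)
        out = np.empty((X.shape[0], self.classes_.size))
        for i, x in enumerate(X):
            node = self.tree_
            while not node.is_leaf:
                node = node.left if x[node.feature] <= node.threshold else node.right
            out[i] = node.proba()[: self.classes_.size]
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Distance-weighted kNN


class DistanceWeightedKNNClassifier(ClassifierMixin, BaseEstimator):
    """kNN with squared-inverse-distance vote weights.

    Parameters
    ----------
    k : int, default 84
        Neighbourhood size; the effective k is min(k, n_train). Neighbours
        tied with the k-th distance are all included.
    metric : {"euclidean", "cityblock", "chebyshev"}, default "euclidean"
    weighting : {"squared_inverse", "inverse", "equal"}, default "squared_inverse"
    standardize : bool, default True
        Centre/scale features by training mean and sample SD.
    """

    def __init__(
        self,
        k: int = 84,
        metric: str = "euclidean",
        weighting: str = "squared_inverse",
        standardize: bool = True,
    ):
        self.k = k
        self.metric = metric
        self.weighting = weighting
        self.standardize = standardize

    def fit(self, X, y):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.weighting not in ("squared_inverse", "inverse", "equal"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        X, y01 = _validate_fit(self, X, y)
        self.scaler_ = (
            standardize_fit(X)
            if self.standardize
            else StandardizationParams(np.zeros(X.shape[1]), np.ones(X.shape[1]))
        )
        self.X_train_ = standardize_apply(self.scaler_, X)
        self.y_train_ = y01
        return self

    def _vote(self, d: np.ndarray) -> np.ndarray:
        """Per-class vote mass for one query given distances to train rows."""
        n_classes = max(self.classes_.size, 2)
        kk = min(self.k, d.size)
        dk = np.partition(d, kk - 1)[kk - 1]
        sel = d <= dk
        votes = np.zeros(n_classes)
        zero = sel & (d == 0.0)
        if zero.any():
            for c in range(n_classes):
                votes[c] = int((self.y_train_[zero] == c).sum())
            return votes
        dn = d[sel]
        if self.weighting == "squared_inverse":
            w = 1.0 / dn**2
        elif self.weighting == "inverse":
            w = 1.0 / dn
        else:
            w = np.ones_like(dn)
        yn = self.y_train_[sel]
        for c in range(n_classes):
            votes[c] = w[yn == c].sum()
        return votes

    def predict_proba(self, X):
        check_is_fitted(self, "X_train_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: {X.shape[1]} != {self.n_features_in_}"
            )
        Xs = standardize_apply(self.scaler_, X)
        D = cdist(Xs, self.X_train_, metric=self.metric)
        out = np.empty((X.shape[0], self.classes_.size))
        for i in range(X.shape[0]):
            votes = self._vote(D[i])[: self.classes_.size]
            out[i] = votes / votes.sum() if votes.sum() else 1.0 / self.classes_.size
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Random-feature kernel logistic regression


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class RandomFeatureKernelLogistic(ClassifierMixin, BaseEstimator):
    """Gaussian-kernel logistic classification via random cosine features.

    The map z(x) = sqrt(2/D) * cos(W x / sigma + b), with W_ij ~ N(0, 1) and
    b_i ~ U[0, 2*pi), satisfies E[z(x)^T z(x')] = exp(-||x - x'||^2 /
    (2 sigma^2)), so a linear logistic head on z approximates Gaussian-kernel
    logistic regression. The objective

        mean log-loss + lambda * ||w||^2 / 2   (intercept unpenalised)

    is minimised by damped Newton iteration, stopping at gradient norm below
    ``tol`` or at ``max_iter``.

    Parameters
    ----------
    n_components : int, default 115
        Expansion dimension D.
    reg_lambda : float, default 0.55035
        L2 regularisation strength lambda.
    kernel_scale : float or "auto", default "auto"
        Gaussian kernel bandwidth sigma; "auto" uses sqrt(n_features).
    max_iter : int, default 1000
    tol : float, default 1e-8
    random_state : int, default 0
        Seed for W and b; fits are deterministic given (data, params, seed).
    standardize : bool, default True
    """

    def __init__(
        self,
        n_components: int = 115,
        reg_lambda: float = 0.55035,
        kernel_scale: float | str = "auto",
        max_iter: int = 1000,
        tol: float = 1e-8,
        random_state: int = 0,
        standardize: bool = True,
    ):
        self.n_components = n_components
        self.reg_lambda = reg_lambda
        self.kernel_scale = kernel_scale
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.standardize = standardize

    def _map(self, X: np.ndarray) -> np.ndarray:
        return math.sqrt(2.0 / self.n_components) * np.cos(
            X @ self.W_.T / self.kernel_scale_ + self.b_
        )

    def transform(self, X):
        """Random-feature map of (standardized) X; shape (n, D)."""
        check_is_fitted(self, "W_")
        X = check_array(X)
        return self._map(standardize_apply(self.scaler_, X))

    def fit(self, X, y):
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        X, y01 = _validate_fit(self, X, y)
        if self.classes_.size < 2:
            raise ValueError("both classes must be present to fit")
        self.scaler_ = (
            standardize_fit(X)
            if self.standardize
            else StandardizationParams(np.zeros(X.shape[1]), np.ones(X.shape[1]))
        )
        Xs = standardize_apply(self.scaler_, X)
        d = X.shape[1]
        self.kernel_scale_ = (
            math.sqrt(d) if self.kernel_scale == "auto" else float(self.kernel_scale)
        )
        if self.kernel_scale_ <= 0:
            raise ValueError("kernel_scale must be > 0")
        rng = np.random.default_rng(self.random_state)
        self.W_ = rng.standard_normal((self.n_components, d))
        self.b_ = rng.uniform(0.0, 2.0 * math.pi, self.n_components)
        Z = self._map(Xs)

        n, D = Z.shape
        lam = self.reg_lambda
        theta = np.zeros(D + 1)  # [w, intercept]
        Z1 = np.hstack([Z, np.ones((n, 1))])

        def loss_grad(th):
            m = Z1 @ th
            p = _sigmoid(m)
            ll = np.logaddexp(0.0, m) - y01 * m  # -log-likelihood per sample
            loss = ll.mean() + lam * (th[:-1] @ th[:-1]) / 2.0
            g = Z1.T @ (p - y01) / n
            g[:-1] += lam * th[:-1]
            return loss, g, p

        loss, g, p = loss_grad(theta)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite logistic loss")
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            if np.linalg.norm(g) < self.tol:
                break
            w_h = np.clip(p * (1.0 - p), 1e-12, None)
            H = (Z1 * w_h[:, None]).T @ Z1 / n
            H[np.arange(D), np.arange(D)] += lam
            H[np.arange(D + 1), np.arange(D + 1)] += 1e-12
            step = np.linalg.solve(H, g)
            t = 1.0
            for _ in range(50):  # backtracking keeps Newton monotone
                new_loss, new_g, new_p = loss_grad(theta - t * step)
                if np.isfinite(new_loss) and new_loss <= loss + 1e-14:
                    break
                t /= 2.0
            theta = theta - t * step
            loss, g, p = new_loss, new_g, new_p
        self.coef_ = theta[:-1]
        self.intercept_ = float(theta[-1])
        self.n_iter_ = n_iter
        self.converged_ = bool(np.linalg.norm(g) < self.tol)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        return self.transform(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# Functional wrappers (thin; the estimators above are the implementation)


def fit_tree(X, y, max_splits: int = 100) -> GiniTreeClassifier:
    return GiniTreeClassifier(max_splits=max_splits).fit(X, y)


def predict_tree(model: GiniTreeClassifier, X):
    return model.predict(X)


def fit_knn(
    X, y, k: int = 84, metric: str = "euclidean", weighting: str = "squared_inverse"
) -> DistanceWeightedKNNClassifier:
    return DistanceWeightedKNNClassifier(k=k, metric=metric, weighting=weighting).fit(X, y)


def predict_knn(model: DistanceWeightedKNNClassifier, X):
    return model.predict(X)


def fit_kernel_logistic(
    X,
    y,
    n_components: int = 115,
    reg_lambda: float = 0.55035,
    kernel_scale: float | str = "auto",
    max_iter: int = 1000,
    seed: int = 0,
) -> RandomFeatureKernelLogistic:
    return RandomFeatureKernelLogistic(
        n_components=n_components,
        reg_lambda=reg_lambda,
        kernel_scale=kernel_scale,
        max_iter=max_iter,
        random_state=seed,
    ).fit(X, y)


def predict_kernel(model: RandomFeatureKernelLogistic, X):
    """Return (labels, class-1 probabilities)."""
    return model.predict(X), model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# JSON serialization


def _tree_node_to_dict(node: _TreeNode) -> dict:
    d = {"counts": node.counts.tolist()}
    if not node.is_leaf:
        d.update(
            feature=node.feature,
            threshold=node.threshold,
            left=_tree_node_to_dict(node.left),
            right=_tree_node_to_dict(node.right),
        )
    return d


def _tree_node_from_dict(d: dict) -> _TreeNode:
    node = _TreeNode(counts=np.asarray(d["counts"], dtype=float))
    if "feature" in d:
        node.feature = int(d["feature"])
        node.threshold = float(d["threshold"])
        node.left = _tree_node_from_dict(d["left"])
        node.right = _tree_node_from_dict(d["right"])
    return node


def model_to_dict(model) -> dict:
    """Serialise a fitted estimator to a JSON-compatible dict."""
    common = {
        "params": model.get_params(),
        "classes": np.asarray(model.classes_).tolist(),
        "n_features_in": int(model.n_features_in_),
    }
    if isinstance(model, GiniTreeClassifier):
        return {
            "type": "tree",
            **common,
            "n_splits": model.n_splits_,
            "root": _tree_node_to_dict(model.tree_),
        }
    if isinstance(model, DistanceWeightedKNNClassifier):
        return {
            "type": "knn",
            **common,
            "center": model.scaler_.center.tolist(),
            "scale": model.scaler_.scale.tolist(),
            "X_train": model.X_train_.tolist(),
            "y_train": model.y_train_.tolist(),
        }
    if isinstance(model, RandomFeatureKernelLogistic):
        return {
            "type": "kernel",
            **common,
            "center": model.scaler_.center.tolist(),
            "scale": model.scaler_.scale.tolist(),
            "W": model.W_.tolist(),
            "b": model.b_.tolist(),
            "kernel_scale": model.kernel_scale_,
            "coef": model.coef_.tolist(),
            "intercept": model.intercept_,
        }
    # HPF threshold classifier is serialised by duck type to avoid an import cycle
    if hasattr(model, "cutoff_"):
        return {
            "type": "hpf",
            **common,
            "cutoff": model.cutoff_,
            "youden_j": model.youden_j_,
        }
    raise TypeError(f"cannot serialise model of type {type(model).__name__}")


def model_from_dict(d: dict):
    """Rebuild a fitted estimator from :func:`model_to_dict` output."""
    from .hpf import HPFThresholdClassifier  # local import: avoids cycle

    kind = d["type"]
    makers = {
        "tree": GiniTreeClassifier,
        "knn": DistanceWeightedKNNClassifier,
        "kernel": RandomFeatureKernelLogistic,
        "hpf": HPFThresholdClassifier,
    }
    if kind not in makers:
        raise ValueError(f"unknown model type {kind!r}")
    model = makers[kind](**d["params"])
    model.classes_ = np.asarray(d["classes"])
    model.n_features_in_ = int(d["n_features_in"])
    if kind == "tree":
        model.tree_ = _tree_node_from_dict(d["root"])
        model.n_splits_ = int(d["n_splits"])
    elif kind == "knn":
        model.scaler_ = StandardizationParams(
            np.asarray(d["center"]), np.asarray(d["scale"])
        )
        model.X_train_ = np.asarray(d["X_train"], dtype=float)
        model.y_train_ = np.asarray(d["y_train"], dtype=int)
    elif kind == "kernel":
        model.scaler_ = StandardizationParams(
            np.asarray(d["center"]), np.asarray(d["scale"])
        )
        model.W_ = np.asarray(d["W"], dtype=float)
        model.b_ = np.asarray(d["b"], dtype=float)
        model.kernel_scale_ = float(d["kernel_scale"])
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
    else:
        model.cutoff_ = float(d["cutoff"])
        model.youden_j_ = float(d["youden_j"])
    return model


def save_model(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path: str | Path):
    return model_from_dict(json.loads(Path(path).read_text()))
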