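"""Linear and non-linear classifiers for two-class FNC feature vectors.

The closed-form classifiers (linear/quadratic Gaussian discriminants,
Fisher's linear discriminant, Gaussian naive Bayes, k-nearest neighbors,
the classic perceptron, a binary decision tree) are implemented here
directly; the SVMs and the logistic classifier are backed by
scikit-learn's convex solvers.  All classifiers use equal class priors —
the study design is balanced and deliberately ignores the population
prevalence — and expose a small sklearn-style ``fit``/``predict``
surface plus a hyperparameter grid for LOOCV selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

__all__ = [
    "Classifier",
    "LinearDiscriminant",
    "FisherDiscriminant",
    "LogisticClassifier",
    "PerceptronClassifier",
    "LinearSVM",
    "KNearestNeighbors",
    "GaussianNaiveBayes",
    "QuadraticDiscriminant",
    "DecisionTree",
    "MLPBackprop",
    "RBFNetwork",
    "KernelSVM",
    "default_roster",
    "sigma_grid_from_data",
]

_RIDGE = 1e-6


class Classifier:
    """Minimal estimator interface: ``fit(X, y) -> self``, ``predict(X)``.

    Subclasses declare ``param_grid`` (a list of hyperparameter dicts
    ordered from simplest to most complex — LOOCV tie-breaking picks the
    first minimizer) and ``nonlinear``.
    """

    name: str = "classifier"
    nonlinear: bool = False
    param_grid: list = []

    def get_params(self) -> dict:
        return dict(self._params)

    def clone_with(self, **params) -> "Classifier":
        merged = {**self._params, **params}
        return type(self)(**merged)

    def fit(self, X, y):  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, X):  # pragma: no cover - interface
        raise NotImplementedError

    def error_rate(self, X, y) -> float:
        return float(np.mean(self.predict(X) != np.asarray(y)))


def _check_xy(X, y):
    X = np.asarray(X, float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("two-class problems only")
    return X, y, classes


def _regularized_cov(Xc: np.ndarray) -> np.ndarray:
    """Sample covariance with a ridge bump when (near-)singular."""
    n, d = Xc.shape
    C = (Xc.T @ Xc) / max(n - 1, 1)
    lam = np.linalg.eigvalsh(C)
    if lam.min() < _RIDGE * max(lam.max(), 1.0):
        C = C + _RIDGE * max(lam.max(), 1.0) * np.eye(d)
    return C


class LinearDiscriminant(Classifier):
    """Gaussian classes with a shared covariance matrix (LDC).

    The pooled covariance is the prior-weighted average of the class
    covariances; with equal priors the decision rule is the linear
    boundary w.x + b > 0.  A ridge term is added when the pooled
    covariance is singular (more features than training subjects).
    """

    name = "LDC"

    def __init__(self):
        self._params = {}

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        mus, covs = [], []
        for c in classes:
            Xi = X[y == c]
            mus.append(Xi.mean(axis=0))
            covs.append(_regularized_cov(Xi - Xi.mean(axis=0)))
        self.means_ = np.asarray(mus)
        pooled = 0.5 * covs[0] + 0.5 * covs[1]          # equal priors
        P = np.linalg.inv(pooled)
        m0, m1 = self.means_
        self.w_ = P @ (m1 - m0)
        self.b_ = -0.5 * (m1 + m0) @ self.w_
        return self

    def decision_function(self, X):
        return np.asarray(X, float) @ self.w_ + self.b_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class FisherDiscriminant(Classifier):
    """Fisher's linear discriminant: project onto the direction maximizing
    between-class over within-class scatter, threshold midway between the
    projected class means."""

    name = "Fisher"

    def __init__(self):
        self._params = {}

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
        Sw = _regularized_cov(X0 - m0) * max(len(X0) - 1, 1) \
            + _regularized_cov(X1 - m1) * max(len(X1) - 1, 1)
        self.w_ = np.linalg.solve(Sw, m1 - m0)
        self.threshold_ = 0.5 * (m0 + m1) @ self.w_
        return self

    def decision_function(self, X):
        return np.asarray(X, float) @ self.w_ - self.threshold_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class LogisticClassifier(Classifier):
    """Logistic regression; the fit is delegated to scikit-learn's convex
    solver, the decision rule is the sign of w0 + sum(wi Xi)."""

    name = "Logistic"

    def __init__(self, C: float = 1.0):
        self._params = {"C": C}
        self.C = C

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self._lr = LogisticRegression(C=self.C, max_iter=5000)
        self._lr.fit(X, y)
        return self

    def predict(self, X):
        return self._lr.predict(np.asarray(X, float))

    @property
    def weights(self):
        return self._lr.coef_.ravel()

    @property
    def intercept(self):
        return float(self._lr.intercept_[0])


class PerceptronClassifier(Classifier):
    """Classic perceptron learning rule: cycle through the training set in
    a fixed order, correcting each misclassification, until an error-free
    pass or the epoch cap.  Converges in finitely many updates on linearly
    separable data."""

    name = "Perceptron"

    def __init__(self, max_epochs: int = 1000, learning_rate: float = 1.0):
        self._params = {"max_epochs": max_epochs, "learning_rate": learning_rate}
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        t = np.where(y == classes[1], 1.0, -1.0)
        Xa = np.hstack([np.ones((len(X), 1)), X])
        w = np.zeros(Xa.shape[1])
        self.n_updates_ = 0
        self.converged_ = False
        for _ in range(self.max_epochs):
            errors = 0
            for xi, ti in zip(Xa, t):
                if ti * (w @ xi) <= 0:
                    w = w + self.learning_rate * ti * xi
                    errors += 1
                    self.n_updates_ += 1
            if errors == 0:
                self.converged_ = True
                break
        self.w_ = w
        return self

    def predict(self, X):
        Xa = np.hstack([np.ones((len(X), 1)), np.asarray(X, float)])
        return self.classes_[(Xa @ self.w_ > 0).astype(int)]


class LinearSVM(Classifier):
    """Maximum-margin linear classifier with soft margin C (scikit-learn's
    SVC with a linear kernel)."""

    name = "LinearSVM"
    param_grid = [{"C": c} for c in (0.1, 1.0, 10.0, 100.0)]

    def __init__(self, C: float = 1.0):
        self._params = {"C": C}
        self.C = C

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self._svc = SVC(kernel="linear", C=self.C)
        self._svc.fit(X, y)
        return self

    def predict(self, X):
        return self._svc.predict(np.asarray(X, float))


class KNearestNeighbors(Classifier):
    """k-nearest-neighbor majority vote with the Euclidean metric.

    Distance ties and vote ties are resolved deterministically (lower
    training index, then lower class label)."""

    name = "KNN"
    nonlinear = True
    param_grid = [{"k": k} for k in (1, 3, 5, 7, 9)]

    def __init__(self, k: int = 3):
        self._params = {"k": k}
        self.k = k

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self.X_, self.y_ = X, y
        if self.k > len(y):
            raise ValueError(f"k={self.k} exceeds training size {len(y)}")
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        d = np.linalg.norm(X[:, None, :] - self.X_[None, :, :], axis=2)
        nn = np.argsort(d, axis=1, kind="stable")[:, :self.k]
        votes = self.y_[nn]
        out = np.empty(len(X), dtype=int)
        for i, v in enumerate(votes):
            counts = [(v == c).sum() for c in self.classes_]
            out[i] = self.classes_[int(np.argmax(counts))]
        return out


class GaussianNaiveBayes(Classifier):
    """Naive Bayes with per-feature Gaussian densities and equal priors."""

    name = "NaiveBayes"
    nonlinear = True

    def __init__(self, var_floor: float = 1e-9):
        self._params = {"var_floor": var_floor}
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self.mu_ = np.stack([X[y == c].mean(axis=0) for c in classes])
        self.var_ = np.stack([
            np.maximum(X[y == c].var(axis=0), self.var_floor) for c in classes
        ])
        return self

    def _log_joint(self, X):
        X = np.asarray(X, float)
        lj = np.empty((len(X), 2))
        for k in range(2):
            lj[:, k] = -0.5 * np.sum(
                np.log(2 * np.pi * self.var_[k])
                + (X - self.mu_[k]) ** 2 / self.var_[k], axis=1)
        return lj                                        # equal priors drop out

    def predict_proba(self, X):
        lj = self._log_joint(X)
        lj -= lj.max(axis=1, keepdims=True)
        p = np.exp(lj)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._log_joint(X), axis=1)]


class QuadraticDiscriminant(Classifier):
    """Gaussian classes with distinct covariance matrices (QDC): the
    decision boundary is quadratic.  Ridge-regularized when a class
    covariance is singular."""

    name = "QDC"
    nonlinear = True

    def __init__(self):
        self._params = {}

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self.mu_, self.prec_, self.logdet_ = [], [], []
        for c in classes:
            Xi = X[y == c]
            mu = Xi.mean(axis=0)
            C = _regularized_cov(Xi - mu)
            self.mu_.append(mu)
            self.prec_.append(np.linalg.inv(C))
            self.logdet_.append(np.linalg.slogdet(C)[1])
        return self

    def _scores(self, X):
        X = np.asarray(X, float)
        sc = np.empty((len(X), 2))
        for k in range(2):
            d = X - self.mu_[k]
            sc[:, k] = -0.5 * (np.einsum("ij,jk,ik->i", d, self.prec_[k], d)
                               + self.logdet_[k])
        return sc

    def decision_function(self, X):
        sc = self._scores(X)
        return sc[:, 1] - sc[:, 0]

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]


class DecisionTree(Classifier):
    """Greedy binary decision tree on axis-aligned thresholds.

    Split scores: ``info_gain`` (entropy reduction) or ``fisher`` (the
    univariate Fisher ratio of the candidate feature: squared class-mean
    separation over within-class variance, with the threshold then chosen
    to minimize misclassification).  The tree is grown fully subject to a
    minimum leaf size; no cost-complexity pruning.
    """

    name = "DecisionTree"
    nonlinear = True

    def __init__(self, criterion: str = "info_gain", max_depth: int | None = None,
                 min_leaf: int = 2):
        if criterion not in ("info_gain", "fisher"):
            raise ValueError(f"unknown criterion {criterion!r}")
        self._params = {"criterion": criterion, "max_depth": max_depth,
                        "min_leaf": min_leaf}
        self.criterion = criterion
        self.max_depth = max_depth
        self.min_leaf = min_leaf

    @staticmethod
    def _entropy(y):
        n = len(y)
        if n == 0:
            return 0.0
        p = np.bincount(y).astype(float)
        p = p[p > 0] / n
        return float(-(p * np.log2(p)).sum())

    def _best_split(self, X, y):
        n, d = X.shape
        best = None
        if self.criterion == "fisher":
            # rank features by the univariate Fisher ratio, then pick the
            # misclassification-minimizing threshold on the best feature
            ratios = np.zeros(d)
            for j in range(d):
                x0, x1 = X[y == 0, j], X[y == 1, j]
                if len(x0) == 0 or len(x1) == 0:
                    continue
                within = x0.var() * len(x0) + x1.var() * len(x1)
                ratios[j] = (x0.mean() - x1.mean()) ** 2 / (within / n + 1e-12)
            feats = [int(np.argmax(ratios))]
        else:
            feats = range(d)
        for j in feats:
            order = np.argsort(X[:, j], kind="stable")
            xs, ys = X[order, j], y[order]
            for i in range(self.min_leaf, n - self.min_leaf + 1):
                if i < len(xs) and xs[i] == xs[i - 1]:
                    continue
                thr = 0.5 * (xs[i - 1] + xs[i]) if i < len(xs) else xs[-1]
                left, right = ys[:i], ys[i:]
                if self.criterion == "info_gain":
                    score = self._entropy(y) - (
                        len(left) * self._entropy(left)
                        + len(right) * self._entropy(right)) / n
                else:
                    score = -(np.sum(left != np.bincount(left).argmax())
                              + np.sum(right != np.bincount(right).argmax()))
                # ties (e.g. all zero-gain splits on XOR data) resolve
                # toward the most balanced split, then the lower feature
                key = (round(float(score), 12), -abs(i - n / 2))
                if best is None or key > best[0]:
                    best = (key, j, thr)
        return best

    def _grow(self, X, y, depth):
        node = {"n": len(y), "pred": int(np.bincount(y).argmax())}
        if (len(np.unique(y)) == 1 or len(y) < 2 * self.min_leaf
                or (self.max_depth is not None and depth >= self.max_depth)):
            return node
        split = self._best_split(X, y)
        if split is None:
            return node
        _, j, thr = split
        mask = X[:, j] <= thr
        if mask.sum() < self.min_leaf or (~mask).sum() < self.min_leaf:
            return node
        node.update({
            "feature": j, "threshold": float(thr),
            "left": self._grow(X[mask], y[mask], depth + 1),
            "right": self._grow(X[~mask], y[~mask], depth + 1),
        })
        return node

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        y01 = (y == classes[1]).astype(int)
        self.tree_ = self._grow(X, y01, 0)
        return self

    def _predict_one(self, x):
        node = self.tree_
        while "feature" in node:
            node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
        return node["pred"]

    def predict(self, X):
        X = np.asarray(X, float)
        return self.classes_[np.array([self._predict_one(x) for x in X])]

    def n_nodes(self) -> int:
        def count(node):
            if "feature" not in node:
                return 1
            return 1 + count(node["left"]) + count(node["right"])
        return count(self.tree_)


class MLPBackprop(Classifier):
    """One-hidden-layer perceptron trained by plain gradient-descent
    backpropagation (tanh hidden units, sigmoid output, cross-entropy
    loss), with a fixed epoch count and seed for determinism.  Inputs are
    standardized internally."""

    name = "MLP"
    nonlinear = True
    param_grid = [{"n_hidden": h} for h in (2, 4, 8)]

    def __init__(self, n_hidden: int = 4, learning_rate: float = 0.05,
                 epochs: int = 500, seed: int = 0):
        self._params = {"n_hidden": n_hidden, "learning_rate": learning_rate,
                        "epochs": epochs, "seed": seed}
        self.n_hidden = n_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.seed = seed

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self.mu_, self.sd_ = X.mean(axis=0), X.std(axis=0)
        self.sd_[self.sd_ == 0] = 1.0
        Xs = (X - self.mu_) / self.sd_
        t = (y == classes[1]).astype(float)
        rng = np.random.default_rng(self.seed)
        n, d = Xs.shape
        W1 = rng.standard_normal((d, self.n_hidden)) / np.sqrt(d)
        b1 = np.zeros(self.n_hidden)
        W2 = rng.standard_normal(self.n_hidden) / np.sqrt(self.n_hidden)
        b2 = 0.0
        lr = self.learning_rate
        for _ in range(self.epochs):
            H = np.tanh(Xs @ W1 + b1)
            p = 1.0 / (1.0 + np.exp(-(H @ W2 + b2)))
            delta = (p - t) / n                        # dL/dlogit
            gW2 = H.T @ delta
            gb2 = delta.sum()
            dH = np.outer(delta, W2) * (1.0 - H ** 2)
            gW1 = Xs.T @ dH
            gb1 = dH.sum(axis=0)
            W2 -= lr * gW2
            b2 -= lr * gb2
            W1 -= lr * gW1
            b1 -= lr * gb1
        self.W1_, self.b1_, self.W2_, self.b2_ = W1, b1, W2, b2
        return self

    def decision_function(self, X):
        Xs = (np.asarray(X, float) - self.mu_) / self.sd_
        H = np.tanh(Xs @ self.W1_ + self.b1_)
        return H @ self.W2_ + self.b2_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class RBFNetwork(Classifier):
    """Radial-basis-function network: k-means centers, Gaussian hidden
    activations with a shared width, and a ridge least-squares output
    layer."""

    name = "RBFNet"
    nonlinear = True
    param_grid = [{"n_centers": c} for c in (4, 8)]

    def __init__(self, n_centers: int = 8, width_scale: float = 1.0,
                 ridge: float = 1e-6, seed: int = 0):
        self._params = {"n_centers": n_centers, "width_scale": width_scale,
                        "ridge": ridge, "seed": seed}
        self.n_centers = n_centers
        self.width_scale = width_scale
        self.ridge = ridge
        self.seed = seed

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        t = np.where(y == classes[1], 1.0, -1.0)
        k = min(self.n_centers, len(X))
        km = KMeans(n_clusters=k, n_init=5, random_state=self.seed).fit(X)
        self.centers_ = km.cluster_centers_
        if k > 1:
            dd = np.linalg.norm(self.centers_[:, None] - self.centers_[None], axis=2)
            width = self.width_scale * dd[dd > 0].mean()
        else:
            width = self.width_scale
        self.width_ = max(width, 1e-6)
        Phi = self._design(X)
        A = Phi.T @ Phi + self.ridge * np.eye(Phi.shape[1])
        self.w_ = np.linalg.solve(A, Phi.T @ t)
        return self

    def _design(self, X):
        X = np.asarray(X, float)
        d2 = ((X[:, None, :] - self.centers_[None]) ** 2).sum(axis=2)
        Phi = np.exp(-d2 / (2.0 * self.width_ ** 2))
        return np.hstack([Phi, np.ones((len(X), 1))])

    def decision_function(self, X):
        return self._design(X) @ self.w_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def _unsquared_rbf_kernel(sigma: float):
    def k(A, B):
        d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
        return np.exp(-d / sigma)
    return k


class KernelSVM(Classifier):
    """Kernel SVM (scikit-learn SVC backend).

    ``kind='rbf'`` uses the standard squared-exponential kernel
    exp(−‖xi−x‖²/(2σ²)); ``unsquared_exponent=True`` selects the
    exponential (unsquared-norm) form exp(−‖xi−x‖/σ) instead.
    ``kind='polynomial'`` uses (xi·x + 1)^p.
    """

    name = "KernelSVM"
    nonlinear = True

    def __init__(self, kind: str = "rbf", C: float = 1.0, sigma: float = 1.0,
                 degree: int = 3, unsquared_exponent: bool = False):
        if kind not in ("rbf", "polynomial"):
            raise ValueError(f"unknown kernel {kind!r}")
        if sigma <= 0 or C <= 0 or degree < 1:
            raise ValueError("require sigma > 0, C > 0, degree >= 1")
        self._params = {"kind": kind, "C": C, "sigma": sigma, "degree": degree,
                        "unsquared_exponent": unsquared_exponent}
        self.kind = kind
        self.C = C
        self.sigma = sigma
        self.degree = degree
        self.unsquared_exponent = unsquared_exponent
        self.name = "SVM-RBF" if kind == "rbf" else "SVM-Poly"

    def _make_svc(self):
        if self.kind == "rbf":
            if self.unsquared_exponent:
                return SVC(kernel=_unsquared_rbf_kernel(self.sigma), C=self.C)
            return SVC(kernel="rbf", gamma=1.0 / (2.0 * self.sigma ** 2), C=self.C)
        return SVC(kernel="poly", degree=self.degree, gamma=1.0, coef0=1.0, C=self.C)

    def fit(self, X, y):
        X, y, classes = _check_xy(X, y)
        self.classes_ = classes
        self._svc = self._make_svc()
        self._svc.fit(X, y)
        return self

    def predict(self, X):
        return self._svc.predict(np.asarray(X, float))


def sigma_grid_from_data(X, quantiles=(0.1, 0.25, 0.5, 0.75, 0.9)):
    """RBF width candidates: quantiles of the pairwise training-sample
    Euclidean distances."""
    X = np.asarray(X, float)
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    d = d[np.triu_indices(len(X), k=1)]
    return [float(q) for q in np.quantile(d, quantiles)]


def default_roster(X_train=None, seed: int = 0):
    """The full classifier roster with its hyperparameter grids.

    Returns a list of ``(classifier, grid)`` tuples; grids are ordered
    simple-to-complex so that LOOCV ties resolve toward the simpler model.
    RBF widths are set from training-distance quantiles when ``X_train``
    is given.
    """
    sigmas = sigma_grid_from_data(X_train) if X_train is not None else [1.0]
    roster = [
        (LinearDiscriminant(), None),
        (FisherDiscriminant(), None),
        (LogisticClassifier(), None),
        (PerceptronClassifier(), None),
        (LinearSVM(), LinearSVM.param_grid),
        (KNearestNeighbors(), KNearestNeighbors.param_grid),
        (GaussianNaiveBayes(), None),
        (QuadraticDiscriminant(), None),
        (DecisionTree(), None),
        (MLPBackprop(seed=seed), MLPBackprop.param_grid),
        (RBFNetwork(seed=seed), RBFNetwork.param_grid),
        (KernelSVM(kind="rbf"),
         [{"C": c, "sigma": s} for c in (0.1, 1.0, 10.0, 100.0) for s in sigmas]),
        (KernelSVM(kind="polynomial"),
         [{"C": c, "degree": p} for c in (0.1, 1.0, 10.0, 100.0) for p in (2, 3)]),
    ]
    return roster
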