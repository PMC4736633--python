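"""Uniform regressor interface over the workflow's learner zoo.

A native inverse-distance-weighted kNN, the in-house RVM, and
scikit-learn adapters for the random forest, RBF support vector and
gradient-boosting baselines, each preconfigured with the classical
hyperparameters used for the rat acute-toxicity benchmark (RF: 230
trees, 105 predictors per node; SVM: sigma 0.03125, C 2, epsilon 0.05;
boosting: shrinkage 0.1, depth 7, 69 rounds; RVM: Laplacian kernel,
width 0.044).  Unknown learner names raise an error listing the
registry; external engines (e.g. approximate GP or perceptron-ensemble
implementations) can join the consensus through ``register_learner``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.svm import SVR

from toxqsar import rvm as rvm_core

__all__ = [
    "LearnerSpec",
    "Regressor",
    "fit_learner",
    "knn_predict",
    "register_learner",
    "available_learners",
    "default_spec",
    "DEFAULT_HYPERPARAMETERS",
]


@dataclass(frozen=True)
class LearnerSpec:
    """A learner name plus hyperparameter overrides."""

    name: str
    hyperparameters: dict = field(default_factory=dict)


class Regressor(Protocol):
    metadata: dict
    feature_names: list[str] | None

    def predict(self, X) -> np.ndarray: ...


DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "knn": {"k": 5},
    "rf": {"n_trees": 230, "predictors_per_node": 105},
    "svm": {"sigma": 0.03125, "C": 2.0, "epsilon": 0.05},
    "gbm": {"shrinkage": 0.1, "max_depth": 7, "n_rounds": 69},
    "rvm": {"kernel": "laplacian", "sigma": 0.044, "parameterization": "multiply"},
    "mean": {},
}


def _coerce_xy(X, y=None):
    names = None
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
    if y is None:
        return X, None, names
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y must align")
    return X, y, names


class _Fitted:
    """Common prediction plumbing: feature-name validation + scaling."""

    def __init__(self, feature_names, metadata):
        self.feature_names = feature_names
        self.metadata = metadata

    def _prepare(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None:
                missing = [c for c in self.feature_names if c not in X.columns]
                if missing:
                    raise ValueError(f"missing features at predict time: {missing}")
                X = X[self.feature_names]
            X = X.to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
        return X


def knn_predict(train_X, train_t, query, k: int) -> float:
    """Inverse-distance-weighted k-nearest-neighbour prediction for one query.

    Weights are 1/d over the k nearest by Euclidean distance; distance
    ties at the k-th neighbour include all tied points, and zero-distance
    neighbours short-circuit to their (unweighted mean) target.
    """
    X, t, _ = _coerce_xy(train_X, train_t)
    q = np.asarray(query, dtype=float).ravel()
    if q.shape[0] != X.shape[1]:
        raise ValueError("query dimension mismatch")
    if not 1 <= k <= X.shape[0]:
        raise ValueError(f"k={k} out of range 1..{X.shape[0]}")
    d = np.sqrt(((X - q) ** 2).sum(axis=1))
    return float(_knn_one(d, t, k))


def _knn_one(d: np.ndarray, t: np.ndarray, k: int) -> float:
    zero = d == 0.0
    if zero.any():
        return float(t[zero].mean())
    kth = np.partition(d, k - 1)[k - 1]
    mask = d <= kth * (1.0 + 1e-12)
    w = 1.0 / d[mask]
    return float(np.sum(w * t[mask]) / np.sum(w))


class KNNRegressor(_Fitted):
    """Native inverse-distance kNN on standardized features."""

    def __init__(self, X, y, k: int, feature_names=None, standardize: bool = True):
        super().__init__(feature_names, {"learner": "knn", "k": k, "standardize": standardize})
        if not 1 <= k <= X.shape[0]:
            raise ValueError(f"k={k} out of range 1..{X.shape[0]}")
        self._mean = X.mean(axis=0) if standardize else np.zeros(X.shape[1])
        scale = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
        scale[scale == 0] = 1.0
        self._scale = scale
        self._X = (X - self._mean) / self._scale
        self._t = y
        self._k = k

    def predict(self, X) -> np.ndarray:
        Xq = (self._prepare(X) - self._mean) / self._scale
        D = cdist(Xq, self._X)
        return np.array([_knn_one(D[i], self._t, self._k) for i in range(Xq.shape[0])])


class MeanRegressor(_Fitted):
    """Predicts the training mean everywhere (null baseline)."""

    def __init__(self, y, feature_names=None):
        super().__init__(feature_names, {"learner": "mean"})
        self._mean = float(np.mean(y))

    def predict(self, X) -> np.ndarray:
        X = self._prepare(X)
        return np.full(X.shape[0], self._mean)


class SklearnRegressor(_Fitted):
    def __init__(self, estimator, X, y, metadata, feature_names=None,
                 standardize: bool = False):
        super().__init__(feature_names, metadata)
        self._mean = X.mean(axis=0) if standardize else np.zeros(X.shape[1])
        scale = X.std(axis=0, ddof=0) if standardize else np.ones(X.shape[1])
        scale[scale == 0] = 1.0
        self._scale = scale
        self._est = estimator.fit((X - self._mean) / self._scale, y)

    def predict(self, X) -> np.ndarray:
        X = (self._prepare(X) - self._mean) / self._scale
        return np.asarray(self._est.predict(X), dtype=float)


class RVMRegressor(_Fitted):
    """Adapter presenting the sparse Bayesian RVM through the common contract."""

    def __init__(self, X, y, hyper: dict, feature_names=None):
        spec = rvm_core.KernelSpec(
            family=hyper.get("kernel", "laplacian"),
            sigma=hyper.get("sigma", 0.044),
            parameterization=hyper.get("parameterization", "multiply"),
        )
        opts = rvm_core.RVMOptions(
            standardize=hyper.get("standardize", True),
            max_iter=hyper.get("max_iter", 1000),
            tol=hyper.get("tol", 1e-3),
        )
        self.model = rvm_core.fit(X, y, spec, opts)
        super().__init__(
            feature_names,
            {
                "learner": "rvm",
                "kernel": spec.family,
                "sigma": spec.sigma,
                "parameterization": spec.parameterization,
                "n_relevance_vectors": self.model.n_relevance_vectors,
            },
        )

    def predict(self, X) -> np.ndarray:
        return rvm_core.predict(self.model, self._prepare(X))[0]

    def predict_with_variance(self, X) -> tuple[np.ndarray, np.ndarray]:
        return rvm_core.predict(self.model, self._prepare(X))


def _fit_knn(X, y, hyper, seed, names):
    return KNNRegressor(X, y, k=int(hyper["k"]), feature_names=names)


def _fit_mean(X, y, hyper, seed, names):
    return MeanRegressor(y, feature_names=names)


def _fit_rf(X, y, hyper, seed, names):
    max_features = min(int(hyper["predictors_per_node"]), X.shape[1])
    est = RandomForestRegressor(
        n_estimators=int(hyper["n_trees"]),
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    meta = {"learner": "rf", "n_trees": int(hyper["n_trees"]),
            "predictors_per_node": int(hyper["predictors_per_node"]),
            "max_features_used": max_features, "seed": seed}
    return SklearnRegressor(est, X, y, meta, names)


def _fit_svm(X, y, hyper, seed, names):
    # sigma is the multiply-form RBF width: k = exp(-sigma * ||x-y||^2),
    # i.e. sklearn's gamma, applied in standardized feature space.
    est = SVR(kernel="rbf", gamma=float(hyper["sigma"]), C=float(hyper["C"]),
              epsilon=float(hyper["epsilon"]))
    meta = {"learner": "svm", "sigma": float(hyper["sigma"]), "C": float(hyper["C"]),
            "epsilon": float(hyper["epsilon"])}
    return SklearnRegressor(est, X, y, meta, names, standardize=True)


def _fit_gbm(X, y, hyper, seed, names):
    est = GradientBoostingRegressor(
        learning_rate=float(hyper["shrinkage"]),
        max_depth=int(hyper["max_depth"]),
        n_estimators=int(hyper["n_rounds"]),
        random_state=seed,
    )
    meta = {"learner": "gbm", "shrinkage": float(hyper["shrinkage"]),
            "max_depth": int(hyper["max_depth"]), "n_rounds": int(hyper["n_rounds"]),
            "seed": seed}
    return SklearnRegressor(est, X, y, meta, names)


def _fit_rvm(X, y, hyper, seed, names):
    return RVMRegressor(X, y, hyper, feature_names=names)


_REGISTRY: dict[str, Callable] = {
    "knn": _fit_knn,
    "rf": _fit_rf,
    "svm": _fit_svm,
    "gbm": _fit_gbm,
    "rvm": _fit_rvm,
    "mean": _fit_mean,
}


def register_learner(name: str, factory: Callable, defaults: dict | None = None) -> None:
    """Register an external learner adapter.

    ``factory(X, y, hyperparameters, seed, feature_names) -> Regressor``.
    This is the extension slot for engines not shipped here (approximate
    Gaussian processes, perceptron ensembles, external boosting ...).
    """
    _REGISTRY[name] = factory
    DEFAULT_HYPERPARAMETERS.setdefault(name, dict(defaults or {}))


def available_learners() -> list[str]:
    return sorted(_REGISTRY)


def default_spec(name: str) -> LearnerSpec:
    if name not in DEFAULT_HYPERPARAMETERS:
        raise KeyError(f"unknown learner {name!r}; registry: {available_learners()}")
    return LearnerSpec(name, dict(DEFAULT_HYPERPARAMETERS[name]))


def fit_learner(spec: LearnerSpec, X, y, seed: int = 0) -> Regressor:
    """Fit a registered learner; stochastic learners are seed-reproducible."""
    if spec.name not in _REGISTRY:
        raise KeyError(
            f"unknown learner {spec.name!r}; registry: {available_learners()}"
        )
    hyper = dict(DEFAULT_HYPERPARAMETERS.get(spec.name, {}))
    hyper.update(spec.hyperparameters)
    Xa, ya, names = _coerce_xy(X, y)
    reg = _REGISTRY[spec.name](Xa, ya, hyper, seed, names)
    reg.metadata.setdefault("hyperparameters", hyper)
    return reg
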