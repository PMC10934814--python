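"""ε-support-vector regression of CCS on scaled physicochemical features.

The model is deliberately small: min–max scale the features (targets are
left in raw Å²), grid-search ``(C, gamma, epsilon)`` for an RBF-kernel ε-SVR
by 5-fold cross-validated mean relative error, train on the full training
set, and predict through the explicit kernel expansion

    f(x) = sum_i  dual_i * exp(-gamma * ||x_scaled - sv_i||^2) + bias.

The quadratic program behind :func:`train_svr` is solved by scikit-learn's
SVR (libsvm); the scaler, the tuning loop, model persistence and the
prediction path are owned here so a trained model is a self-contained JSON
document independent of any pickle format.

The default hyperparameter grid is
``C in {1e2, 1e3, 1e4, 1e5, 1e6}``, ``gamma in {0.01, 0.1, 1}`` (on scaled
features), ``epsilon in {0.01, 0.1, 1}`` (Å², raw CCS units) — 45
combinations for the single RBF kernel.  Ties in CV error are broken by
grid order: kernel, then C, then gamma, then epsilon, each in the order
listed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR

from .data_model import PropertyDataset

__all__ = [
    "DEFAULT_FEATURES",
    "DEFAULT_GRID",
    "ScalerParams",
    "HyperParams",
    "TrainedModel",
    "DegenerateFeatureError",
    "ModelFormatError",
    "fit_minmax_scaler",
    "grid_points",
    "tune_hyperparameters",
    "train_svr",
    "predict_ccs",
    "save_model",
    "load_model",
]

DEFAULT_FEATURES: tuple[str, str] = ("polarizability", "mz")

#: 1 kernel x 5 C x 3 gamma x 3 epsilon = 45 combinations
DEFAULT_GRID: dict[str, list] = {
    "kernel": ["rbf"],
    "C": [100.0, 1_000.0, 10_000.0, 100_000.0, 1_000_000.0],
    "gamma": [0.01, 0.1, 1.0],
    "epsilon": [0.01, 0.1, 1.0],
}

_MODEL_FORMAT_VERSION = "polarccs-svr-1"


class DegenerateFeatureError(ValueError):
    """A feature is constant on the training data, so min-max scaling fails."""


class ModelFormatError(ValueError):
    """A persisted model file does not match the expected schema."""


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature min/max learned from training data only."""

    features: tuple[str, ...]
    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def transform(self, X: np.ndarray) -> np.ndarray:
        mins = np.asarray(self.mins)
        maxs = np.asarray(self.maxs)
        return (np.asarray(X, dtype=float) - mins) / (maxs - mins)


@dataclass(frozen=True)
class HyperParams:
    kernel: str = "rbf"
    C: float = 1_000.0
    gamma: float = 0.1
    epsilon: float = 0.1


@dataclass
class TrainedModel:
    """Fitted ε-SVR: scaler, hyperparameters and the kernel expansion."""

    features: tuple[str, ...]
    scaler: ScalerParams
    hyper: HyperParams
    support_vectors: np.ndarray  # (n_sv, p) scaled feature rows
    dual_coefficients: np.ndarray  # (n_sv,)
    bias: float
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X_scaled: np.ndarray) -> np.ndarray:
        d2 = cdist(np.atleast_2d(X_scaled), self.support_vectors, metric="sqeuclidean")
        return np.exp(-self.hyper.gamma * d2) @ self.dual_coefficients + self.bias


def _feature_arrays(ds: PropertyDataset, features: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    return ds.feature_matrix(features), ds.ccs_values()


def fit_minmax_scaler(train: PropertyDataset, features: Sequence[str] = DEFAULT_FEATURES) -> ScalerParams:
    """Learn per-feature min/max from training records.

    Scaled training values span exactly [0, 1]; test-time values may fall
    outside that interval (extrapolation is allowed, flagged at prediction).
    """
    X, _ = _feature_arrays(train, features)
    return _fit_scaler_arrays(X, tuple(features))


def _fit_scaler_arrays(X: np.ndarray, features: tuple[str, ...]) -> ScalerParams:
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    for j, name in enumerate(features):
        if maxs[j] <= mins[j]:
            raise DegenerateFeatureError(
                f"feature {name!r} is constant ({mins[j]}) on the training data"
            )
    return ScalerParams(features=tuple(features), mins=tuple(mins), maxs=tuple(maxs))


def grid_points(grid: dict | None = None) -> list[HyperParams]:
    """Expand a grid dict into :class:`HyperParams` in the documented
    iteration order (kernel, C, gamma, epsilon)."""
    g = DEFAULT_GRID if grid is None else grid
    points = []
    for kernel in g.get("kernel", ["rbf"]):
        for C in g.get("C", [1_000.0]):
            for gamma in g.get("gamma", [0.1]):
                for epsilon in g.get("epsilon", [0.1]):
                    points.append(HyperParams(kernel=kernel, C=float(C), gamma=float(gamma), epsilon=float(epsilon)))
    return points


def _relative_errors(pred: np.ndarray, true: np.ndarray) -> np.ndarray:
    return np.abs(pred - true) / true


def _cv_fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle, recorded for reproducibility."""
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(block) for block in np.array_split(perm, folds)]


#: default optimizer iteration cap for the repeated tuning protocol; the
#: extreme-C corner of the grid otherwise spends millions of SMO iterations
#: refining duals far beyond MRE resolution.  -1 means solve to tolerance.
TUNING_MAX_ITER = 50_000


def _fit_raw_svr(
    X_scaled: np.ndarray, y: np.ndarray, hp: HyperParams, max_iter: int = -1, tol: float = 1e-3
) -> SVR:
    svr = SVR(kernel=hp.kernel, C=hp.C, gamma=hp.gamma, epsilon=hp.epsilon,
              max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svr.fit(X_scaled, y)
    return svr


def _cv_score_arrays(
    X: np.ndarray,
    y: np.ndarray,
    hp: HyperParams,
    fold_indices: list[np.ndarray],
    features: tuple[str, ...],
    max_iter: int = -1,
) -> float:
    """Mean CV relative error (fraction, not %); scaler re-fit per fold."""
    n = len(y)
    errors = []
    for val_idx in fold_indices:
        mask = np.ones(n, dtype=bool)
        mask[val_idx] = False
        scaler = _fit_scaler_arrays(X[mask], features)
        svr = _fit_raw_svr(scaler.transform(X[mask]), y[mask], hp, max_iter)
        pred = svr.predict(scaler.transform(X[val_idx]))
        errors.append(_relative_errors(pred, y[val_idx]).mean())
    return float(np.mean(errors))


def tune_hyperparameters(
    train: PropertyDataset,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    features: Sequence[str] = DEFAULT_FEATURES,
    return_details: bool = False,
    max_iter: int = TUNING_MAX_ITER,
):
    """Grid-search hyperparameters by ``folds``-fold cross-validated MRE.

    The scaler is re-fit inside every fold on that fold's training portion,
    so no information leaks from the held-out block.  The selected point is
    the first grid point (in documented order) attaining the minimum mean CV
    relative error.  A single-point grid is returned directly without CV.
    ``max_iter`` caps the SMO iterations per candidate fit (-1 = exact).
    """
    X, y = _feature_arrays(train, features)
    return _tune_arrays(X, y, grid, folds, seed, tuple(features), return_details, max_iter)


def _tune_arrays(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict | None,
    folds: int,
    seed: int,
    features: tuple[str, ...],
    return_details: bool = False,
    max_iter: int = TUNING_MAX_ITER,
):
    points = grid_points(grid)
    if not points:
        raise ValueError("empty hyperparameter grid")
    if len(points) == 1:
        return (points[0], [(points[0], float("nan"))]) if return_details else points[0]
    n = len(y)
    if n < folds:
        raise ValueError(f"{n} records is fewer than {folds} CV folds")
    fold_indices = _cv_fold_indices(n, folds, seed)
    best: HyperParams | None = None
    best_score = np.inf
    table = []
    for hp in points:
        score = _cv_score_arrays(X, y, hp, fold_indices, features, max_iter)
        table.append((hp, score))
        if score < best_score:  # strict: first grid point wins ties
            best_score = score
            best = hp
    return (best, table) if return_details else best


def train_svr(
    train: PropertyDataset,
    hyper: HyperParams,
    features: Sequence[str] = DEFAULT_FEATURES,
    metadata: dict | None = None,
    max_iter: int = -1,
    tol: float = 1e-3,
) -> TrainedModel:
    """Fit the ε-insensitive SVR on min-max-scaled features.

    Targets (CCS, Å²) are not scaled; ``epsilon`` is therefore a tube
    half-width in Å².  By default the quadratic program is solved to the
    optimizer's tolerance (``max_iter=-1``, ``tol`` on the dual optimality
    conditions).
    """
    X, y = _feature_arrays(train, features)
    return _train_arrays(X, y, hyper, tuple(features), metadata, max_iter, tol)


def _train_arrays(
    X: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
    features: tuple[str, ...],
    metadata: dict | None = None,
    max_iter: int = -1,
    tol: float = 1e-3,
) -> TrainedModel:
    if len(y) < 2:
        raise ValueError("need at least 2 training records")
    scaler = _fit_scaler_arrays(X, features)
    svr = _fit_raw_svr(scaler.transform(X), y, hyper, max_iter, tol)
    meta = {"n_train": int(len(y))}
    if metadata:
        meta.update(metadata)
    return TrainedModel(
        features=features,
        scaler=scaler,
        hyper=hyper,
        support_vectors=np.asarray(svr.support_vectors_, dtype=float),
        dual_coefficients=np.asarray(svr.dual_coef_, dtype=float).ravel(),
        bias=float(svr.intercept_[0]),
        metadata=meta,
    )


def predict_ccs(model: TrainedModel, records: PropertyDataset) -> pd.DataFrame:
    """Predict CCS for every record.

    Returns a DataFrame with columns ``compound_id, adduct_type,
    predicted_ccs, extrapolated``; ``extrapolated`` flags records whose
    scaled features fall outside [-0.1, 1.1] (prediction proceeds anyway).
    """
    X = records.feature_matrix(model.features)
    Xs = model.scaler.transform(X)
    pred = model.decision_function(Xs)
    outside = np.any((Xs < -0.1) | (Xs > 1.1), axis=1)
    return pd.DataFrame(
        {
            "compound_id": [rec.compound_id for rec in records],
            "adduct_type": [rec.adduct_type for rec in records],
            "predicted_ccs": pred,
            "extrapolated": outside,
        }
    )


def save_model(model: TrainedModel, path) -> None:
    doc = {
        "version": _MODEL_FORMAT_VERSION,
        "features": list(model.features),
        "scaler": {"min": list(model.scaler.mins), "max": list(model.scaler.maxs)},
        "hyper": asdict(model.hyper),
        "support_vectors": np.asarray(model.support_vectors).tolist(),
        "dual_coefficients": np.asarray(model.dual_coefficients).tolist(),
        "bias": model.bias,
        "metadata": model.metadata,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> TrainedModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: not valid JSON ({exc})") from None
    if not isinstance(doc, dict) or doc.get("version") != _MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: expected version {_MODEL_FORMAT_VERSION!r}, got {doc.get('version')!r}"
        )
    required = ("features", "scaler", "hyper", "support_vectors", "dual_coefficients", "bias")
    missing = [k for k in required if k not in doc]
    if missing:
        raise ModelFormatError(f"{path}: missing fields {missing}")
    features = tuple(doc["features"])
    scaler = ScalerParams(
        features=features, mins=tuple(doc["scaler"]["min"]), maxs=tuple(doc["scaler"]["max"])
    )
    return TrainedModel(
        features=features,
        scaler=scaler,
        hyper=HyperParams(**doc["hyper"]),
        support_vectors=np.asarray(doc["support_vectors"], dtype=float),
        dual_coefficients=np.asarray(doc["dual_coefficients"], dtype=float),
        bias=float(doc["bias"]),
        metadata=doc.get("metadata", {}),
    )
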