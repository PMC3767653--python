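"""Soft-margin SVM training, cross-validation and prediction.

Windows are encoded with VHSE descriptors, each feature column is scaled
linearly to [0, 1] on the training set, and a support-vector classifier
(linear or RBF kernel) separates cleavage (+1) from non-cleavage (-1)
windows.  Hyperparameters are chosen by stratified 10-fold
cross-validation, pooling decision values over folds and maximizing MCC
(ties broken by AUC, then smaller C, then smaller gamma).

The quadratic program is solved by scikit-learn's SVC; the convergence
tolerance plays the role of the termination parameter epsilon.  For the
linear kernel the explicit primal weight vector w = sum_i alpha_i y_i x_i
and bias are materialized so per-position weights can be interpreted.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import metrics as _metrics
from .corpus import CLEAVAGE, SampleSet, position_labels
from .vhse import DEFAULT_SELECTION, encode_window, is_canonical, validate_selection

__all__ = [
    "DEFAULT_SEED",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "ScalerParams",
    "FeatureMatrix",
    "TrainedModel",
    "Prediction",
    "fit_scaler",
    "apply_scaler",
    "featurize",
    "train",
    "cross_validate",
    "predict_windows",
    "evaluate",
    "read_features_csv",
    "write_features_csv",
]

DEFAULT_SEED = 20130909
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-5, 6, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** e for e in range(-7, 4, 2))
DEFAULT_EPSILON = 1e-3

LABEL_CODE = {CLEAVAGE: 1}  # everything else maps to -1


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature training min/max defining the affine map onto [0, 1]."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def ranges(self) -> np.ndarray:
        return self.maxs - self.mins


@dataclass
class FeatureMatrix:
    """Raw descriptor rows with +1/-1 labels and a feature->meaning map.

    ``index_map[j]`` gives the (position label, VHSE component) encoded by
    feature column ``j``; the ordering is position-major, upstream to
    downstream, components ascending.
    """

    X: np.ndarray
    y: np.ndarray
    index_map: list[tuple[str, int]]

    @property
    def feature_names(self) -> list[str]:
        return [f"{pos}_VHSE{comp}" for pos, comp in self.index_map]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("feature matrix and labels are inconsistent")
        if self.X.shape[1] != len(self.index_map):
            raise ValueError("index_map length must equal the feature count")


def build_index_map(half_width: int, selection: Sequence[int]) -> list[tuple[str, int]]:
    sel = validate_selection(selection)
    return [(pos, comp) for pos in position_labels(half_width) for comp in sel]


def featurize(sample_set: SampleSet, selection: Sequence[int] = DEFAULT_SELECTION) -> FeatureMatrix:
    """Encode every window of a sample set; labels become +1 (cleavage) / -1."""
    if not sample_set.samples:
        raise ValueError("cannot featurize an empty sample set")
    X = np.vstack([encode_window(s.window, selection) for s in sample_set.samples])
    y = np.array([LABEL_CODE.get(s.label, -1) for s in sample_set.samples])
    return FeatureMatrix(X, y, build_index_map(sample_set.half_width, selection))


def fit_scaler(X: np.ndarray) -> ScalerParams:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need at least one feature row")
    return ScalerParams(mins=X.min(axis=0), maxs=X.max(axis=0))


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    """Affine map to [0, 1]; unseen values clip; constant columns map to 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.mins.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match scaler ({params.mins.shape[0]})"
        )
    rng = params.ranges
    safe = np.where(rng > 0, rng, 1.0)
    out = (X - params.mins) / safe
    out[:, rng == 0] = 0.0
    return np.clip(out, 0.0, 1.0)


@dataclass
class TrainedModel:
    kernel: str
    C: float
    gamma: float | None
    epsilon: float
    scaler: ScalerParams
    index_map: list[tuple[str, int]]
    half_width: int
    selection: tuple[int, ...]
    intercept: float
    support_vectors: np.ndarray  # scaled-space support vectors
    dual_coef: np.ndarray  # alpha_i * y_i per support vector
    weights: np.ndarray | None = None  # explicit w, linear kernel only
    training_hash: str | None = None

    def decision_function(self, X_raw: np.ndarray) -> np.ndarray:
        """Signed decision values for raw (unscaled) descriptor rows."""
        Xs = apply_scaler(self.scaler, X_raw)
        if self.kernel == "linear":
            return Xs @ self.weights + self.intercept
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            - 2.0 * Xs @ self.support_vectors.T
            + np.sum(self.support_vectors**2, axis=1)[None, :]
        )
        return np.exp(-self.gamma * np.maximum(d2, 0.0)) @ self.dual_coef + self.intercept

    def decision_from_support(self, X_raw: np.ndarray) -> np.ndarray:
        """Decision values via the support-vector expansion (any kernel)."""
        Xs = apply_scaler(self.scaler, X_raw)
        if self.kernel == "linear":
            return (Xs @ self.support_vectors.T) @ self.dual_coef + self.intercept
        return self.decision_function(X_raw)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        doc = {
            "format": "vhsecleave-model-v1",
            "kernel": self.kernel,
            "C": self.C,
            "gamma": self.gamma,
            "epsilon": self.epsilon,
            "half_width": self.half_width,
            "selection": list(self.selection),
            "index_map": [[pos, comp] for pos, comp in self.index_map],
            "scaler": {"mins": self.scaler.mins.tolist(), "maxs": self.scaler.maxs.tolist()},
            "intercept": self.intercept,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "weights": None if self.weights is None else self.weights.tolist(),
            "training_hash": self.training_hash,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "vhsecleave-model-v1":
            raise ValueError(f"unrecognized model file format in {path}")
        return cls(
            kernel=doc["kernel"],
            C=doc["C"],
            gamma=doc["gamma"],
            epsilon=doc["epsilon"],
            scaler=ScalerParams(
                mins=np.asarray(doc["scaler"]["mins"], dtype=float),
                maxs=np.asarray(doc["scaler"]["maxs"], dtype=float),
            ),
            index_map=[(pos, int(comp)) for pos, comp in doc["index_map"]],
            half_width=doc["half_width"],
            selection=tuple(doc["selection"]),
            intercept=doc["intercept"],
            support_vectors=np.asarray(doc["support_vectors"], dtype=float),
            dual_coef=np.asarray(doc["dual_coef"], dtype=float),
            weights=None if doc["weights"] is None else np.asarray(doc["weights"], dtype=float),
            training_hash=doc.get("training_hash"),
        )


def _check_training_inputs(features: FeatureMatrix, kernel: str, C: float, gamma: float | None):
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"kernel must be 'linear' or 'rbf', got {kernel!r}")
    if C <= 0:
        raise ValueError("C must be positive")
    if kernel == "rbf" and (gamma is None or gamma <= 0):
        raise ValueError("gamma must be positive for the RBF kernel")
    if not np.isfinite(features.X).all():
        raise ValueError("features must be finite")
    classes = np.unique(features.y)
    if classes.size < 2:
        raise ValueError("training requires both cleavage and non-cleavage samples")


def train(
    features: FeatureMatrix,
    kernel: str = "linear",
    C: float = 1.0,
    gamma: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
    half_width: int | None = None,
    selection: Sequence[int] = DEFAULT_SELECTION,
    training_hash: str | None = None,
) -> TrainedModel:
    """Fit the [0,1] scaler and the soft-margin SVM on all rows."""
    _check_training_inputs(features, kernel, C, gamma)
    sel = validate_selection(selection)
    if half_width is None:
        half_width = len(features.index_map) // len(sel) // 2
    scaler = fit_scaler(features.X)
    Xs = apply_scaler(scaler, features.X)
    svc = SVC(
        kernel=kernel,
        C=C,
        gamma=gamma if kernel == "rbf" else "scale",
        tol=epsilon,
        shrinking=True,
    )
    svc.fit(Xs, features.y)
    weights = svc.coef_.ravel().copy() if kernel == "linear" else None
    return TrainedModel(
        kernel=kernel,
        C=C,
        gamma=gamma if kernel == "rbf" else None,
        epsilon=epsilon,
        scaler=scaler,
        index_map=list(features.index_map),
        half_width=half_width,
        selection=sel,
        intercept=float(svc.intercept_[0]),
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        weights=weights,
        training_hash=training_hash,
    )


def cross_validate(
    features: FeatureMatrix,
    kernel: str = "linear",
    c_grid: Iterable[float] = DEFAULT_C_GRID,
    gamma_grid: Iterable[float] = DEFAULT_GAMMA_GRID,
    folds: int = 10,
    seed: int = DEFAULT_SEED,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[pd.DataFrame, dict]:
    """Stratified k-fold CV over a hyperparameter grid.

    Decision values are pooled over folds before computing MCC/AUC/Acc/
    Sen/Spe, so each setting gets one metric row.  The scaler is refit
    inside every fold to keep test folds untouched.  Returns the metric
    table and the selected setting (max MCC; ties: AUC, smaller C,
    smaller gamma).
    """
    c_grid = [float(c) for c in c_grid]
    gamma_grid = [float(g) for g in gamma_grid]
    if not c_grid:
        raise ValueError("C grid must be non-empty")
    if kernel == "rbf" and not gamma_grid:
        raise ValueError("gamma grid must be non-empty for the RBF kernel")
    _check_training_inputs(
        features, kernel, c_grid[0], None if kernel == "linear" else gamma_grid[0]
    )
    y = features.y
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    if n_min < folds:
        raise ValueError(
            f"need at least {folds} samples per class for {folds}-fold CV, got {n_min}"
        )
    settings = (
        [(C, None) for C in c_grid]
        if kernel == "linear"
        else list(itertools.product(c_grid, gamma_grid))
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    split = list(skf.split(features.X, y))
    rows = []
    for C, gamma in settings:
        pooled_scores = np.empty(y.shape[0])
        for train_idx, test_idx in split:
            scaler = fit_scaler(features.X[train_idx])
            Xs_train = apply_scaler(scaler, features.X[train_idx])
            Xs_test = apply_scaler(scaler, features.X[test_idx])
            svc = SVC(
                kernel=kernel,
                C=C,
                gamma=gamma if kernel == "rbf" else "scale",
                tol=epsilon,
            )
            svc.fit(Xs_train, y[train_idx])
            pooled_scores[test_idx] = svc.decision_function(Xs_test)
        pred = np.where(pooled_scores > 0, 1, -1)
        rep = _metrics.report(y, pred, pooled_scores)
        rows.append(
            {
                "kernel": kernel,
                "C": C,
                "gamma": np.nan if gamma is None else gamma,
                "MCC": rep.mcc,
                "AUC": rep.auc,
                "Acc": rep.acc,
                "Sen": rep.sen,
                "Spe": rep.spe,
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(rows)),
        key=lambda i: (
            -rows[i]["MCC"],
            -(rows[i]["AUC"] or 0.0),
            rows[i]["C"],
            rows[i]["gamma"] if not np.isnan(rows[i]["gamma"]) else 0.0,
        ),
    )
    best = rows[order[0]]
    selected = {
        "kernel": kernel,
        "C": float(best["C"]),
        "gamma": None if np.isnan(best["gamma"]) else float(best["gamma"]),
        "MCC": best["MCC"],
        "AUC": best["AUC"],
        "Acc": best["Acc"],
        "Sen": best["Sen"],
        "Spe": best["Spe"],
    }
    return table, selected


@dataclass(frozen=True)
class Prediction:
    decision: float | None
    label: str | None
    flag: str | None = None  # set when the item could not be scored


def predict_windows(model: TrainedModel, windows: Sequence[str]) -> list[Prediction]:
    """Score residue windows; malformed items are flagged, not scored."""
    expected = 2 * model.half_width
    out: list[Prediction] = []
    scorable: list[int] = []
    rows: list[np.ndarray] = []
    for i, w in enumerate(windows):
        if len(w) != expected:
            out.append(Prediction(None, None, "wrong_length"))
        elif not is_canonical(w):
            out.append(Prediction(None, None, "noncanonical_residue"))
        else:
            out.append(Prediction(None, None, None))  # placeholder
            scorable.append(i)
            rows.append(encode_window(w, model.selection))
    if scorable:
        decisions = model.decision_function(np.vstack(rows))
        for i, d in zip(scorable, decisions):
            out[i] = Prediction(float(d), CLEAVAGE if d > 0 else "non_cleavage")
    return out


def evaluate(model: TrainedModel, features: FeatureMatrix) -> _metrics.MetricsReport:
    """Apply a trained model to labeled feature rows and report metrics."""
    if features.X.shape[1] != len(model.index_map):
        raise ValueError(
            f"feature dimension {features.X.shape[1]} does not match the model "
            f"({len(model.index_map)})"
        )
    scores = model.decision_function(features.X)
    pred = np.where(scores > 0, 1, -1)
    return _metrics.report(features.y, pred, scores)


# -- feature matrix CSV ------------------------------------------------------

def write_features_csv(path, features: FeatureMatrix) -> None:
    """Feature names as header ("P10_VHSE1", ...), final column "label"."""
    df = pd.DataFrame(features.X, columns=features.feature_names)
    df["label"] = features.y
    df.to_csv(path, index=False)


def _parse_feature_name(name: str) -> tuple[str, int]:
    pos, _, comp = name.rpartition("_VHSE")
    if not pos or not comp.isdigit():
        raise ValueError(f"cannot parse feature column name {name!r}")
    return pos, int(comp)


def read_features_csv(path) -> FeatureMatrix:
    """Read a pre-encoded descriptor matrix (final column = +1/-1 label)."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must contain a 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    index_map = [_parse_feature_name(c) for c in df.columns]
    return FeatureMatrix(df.to_numpy(dtype=float), y, index_map)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
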