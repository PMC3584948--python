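"""Linear support-vector regression from feature vectors to local S-scores.

The regressor is a linear epsilon-insensitive SVR.  Hyperparameters (the
error/margin trade-off C and the tube width epsilon) are chosen by grid
search scored with cross-validated Pearson correlation, where folds split
by *target* — residues of one target never appear on both sides of a
split, since models of the same target are strongly correlated.  One
(C, epsilon) pair is selected globally across all folds, and the final
model is refit on the full training set.  Features are standardized to
zero mean / unit variance; the scaler is fit on training folds only
during cross-validation and stored with the model.

The global quality of a model is the sum of its per-residue predicted
S-scores divided by the target sequence length, so unmodeled residues
count as zero and the global score lies in [0, 1].
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GroupKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVR

__all__ = [
    "LinearModel",
    "TrainingSet",
    "train",
    "predict_local",
    "predict_global",
    "save_model",
    "load_model",
    "DEFAULT_C_GRID",
    "DEFAULT_EPS_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)
DEFAULT_EPS_GRID = (0.05, 0.1, 0.2)
SERIALIZATION_VERSION = 1


def layout_fingerprint(names: list[str]) -> str:
    return hashlib.sha256("\n".join(names).encode()).hexdigest()[:16]


@dataclass
class LinearModel:
    """Trained linear SVR: weights/bias on standardized features."""

    weights: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    C: float
    epsilon: float
    fingerprint: str
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.feature_mean = np.asarray(self.feature_mean, float)
        self.feature_scale = np.asarray(self.feature_scale, float)
        if not (len(self.weights) == len(self.feature_mean) == len(self.feature_scale)):
            raise ValueError("weight and scaling vectors must share one length")


@dataclass
class TrainingSet:
    """Feature matrix with target S-scores and a per-row target id."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, float)
        self.y = np.asarray(self.y, float)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2 or len(self.X) != len(self.y) != len(self.groups):
            raise ValueError("X, y and groups must agree in length")
        if not np.all(np.isfinite(self.X)):
            bad = np.where(~np.isfinite(self.X))
            name = (self.feature_names[bad[1][0]] if self.feature_names
                    else f"column {bad[1][0]}")
            raise ValueError(f"non-finite feature value in {name} (row {bad[0][0]})")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite target value")


def _pearson(a, b) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _fit_svr(X, y, C, eps, seed):
    scaler = StandardScaler().fit(X)
    svr = LinearSVR(
        C=C, epsilon=eps, loss="epsilon_insensitive", dual=True,
        max_iter=10000, random_state=seed, tol=1e-4,
    )
    with warnings.catch_warnings():
        # large-C grid points may stop at the iteration cap; the grid
        # search ranks them by held-out correlation regardless
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        svr.fit(scaler.transform(X), y)
    return scaler, svr


def train(
    train_set: TrainingSet,
    C_grid=DEFAULT_C_GRID,
    eps_grid=DEFAULT_EPS_GRID,
    n_folds: int = 5,
    seed: int = 0,
    cv_subsample: int | None = 4000,
) -> tuple[LinearModel, dict]:
    """Grid-search (C, epsilon) with target-level K-fold CV, refit on all data.

    When the training set exceeds ``cv_subsample`` rows, the grid search
    runs on a seeded random row subsample (group labels preserved, so
    folds still split by target); the final model is always refit on the
    full set at the selected hyperparameters.  Returns the final model
    and a CV report: per-combination mean held-out Pearson R and the
    selected hyperparameters.
    """
    unique_groups = np.unique(train_set.groups)
    if len(unique_groups) < 2:
        raise ValueError("need at least 2 targets to build cross-validation folds")
    k = min(n_folds, len(unique_groups))

    X_cv, y_cv, g_cv = train_set.X, train_set.y, train_set.groups
    if cv_subsample is not None and len(y_cv) > cv_subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(y_cv), size=cv_subsample, replace=False)
        X_cv, y_cv, g_cv = X_cv[idx], y_cv[idx], g_cv[idx]

    splitter = GroupKFold(n_splits=k)
    splits = list(splitter.split(X_cv, y_cv, g_cv))

    report = {"grid": [], "n_folds": k}
    best = None
    for C in C_grid:
        for eps in eps_grid:
            fold_rs = []
            for tr, te in splits:
                scaler, svr = _fit_svr(X_cv[tr], y_cv[tr], C, eps, seed)
                pred = svr.predict(scaler.transform(X_cv[te]))
                fold_rs.append(_pearson(pred, y_cv[te]))
            mean_r = float(np.mean(fold_rs))
            report["grid"].append({"C": C, "epsilon": eps, "cv_pearson": mean_r})
            if best is None or mean_r > best[0]:
                best = (mean_r, C, eps)

    _, C, eps = best
    report["selected"] = {"C": C, "epsilon": eps, "cv_pearson": best[0]}
    scaler, svr = _fit_svr(train_set.X, train_set.y, C, eps, seed)
    model = LinearModel(
        weights=svr.coef_.ravel(),
        bias=float(svr.intercept_[0] if np.ndim(svr.intercept_) else svr.intercept_),
        feature_mean=scaler.mean_,
        feature_scale=scaler.scale_,
        C=C,
        epsilon=eps,
        fingerprint=layout_fingerprint(train_set.feature_names),
        feature_names=list(train_set.feature_names),
    )
    return model, report


def predict_local(model: LinearModel, X: np.ndarray,
                  feature_names: list[str] | None = None) -> np.ndarray:
    """Per-residue predicted S-scores, raw linear output clamped to [0, 1]."""
    if feature_names is not None and layout_fingerprint(feature_names) != model.fingerprint:
        raise ValueError("feature layout fingerprint mismatch; refusing to predict")
    X = np.atleast_2d(np.asarray(X, float))
    Z = (X - model.feature_mean) / model.feature_scale
    raw = Z @ model.weights + model.bias
    return np.clip(raw, 0.0, 1.0)


def predict_global(local_s: np.ndarray, target_length: int) -> float:
    """Global quality: sum of local S-scores over the target length."""
    if target_length < len(np.atleast_1d(local_s)):
        raise ValueError("target_length smaller than number of local scores")
    return float(np.sum(local_s) / target_length)


def save_model(model: LinearModel, path) -> None:
    payload = {
        "version": SERIALIZATION_VERSION,
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "C": model.C,
        "epsilon": model.epsilon,
        "fingerprint": model.fingerprint,
        "feature_names": model.feature_names,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> LinearModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    return LinearModel(
        weights=np.array(payload["weights"]),
        bias=payload["bias"],
        feature_mean=np.array(payload["feature_mean"]),
        feature_scale=np.array(payload["feature_scale"]),
        C=payload["C"],
        epsilon=payload["epsilon"],
        fingerprint=payload["fingerprint"],
        feature_names=payload["feature_names"],
    )
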