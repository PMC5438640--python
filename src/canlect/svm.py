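"""RBF-kernel support vector machine on selected tripeptide features.

Thin, contract-enforcing layer over scikit-learn's libsvm-backed ``SVC``:
a trained model remembers exactly which tripeptide columns it consumes
(in order) and refuses silently reordered or mismatched input.  The
kernel is K(x, y) = exp(-g * ||x - y||^2) with regularisation parameter
c; the default working point is c = 2^11, g = 2^-13 and the default
tuning grids are c in 2^{-5..15}, g in 2^{-15..-5}, both stepping by a
factor of 2.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix

DEFAULT_C = 2.0 ** 11
DEFAULT_G = 2.0 ** -13


def fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature min and range for svm-scale-style [-1, 1] scaling.

    Raw tripeptide frequencies have magnitude ~1/(L-2); at kernel widths
    like g = 2^-13 the RBF kernel is numerically constant on such values,
    so each feature is linearly mapped to [-1, 1] using its training-set
    min/max (the classic libsvm svm-scale protocol).  Constant columns
    get range 1 and map to a constant.
    """
    mn = X.min(axis=0)
    mx = X.max(axis=0)
    rng = np.where(mx > mn, mx - mn, 1.0)
    return mn, rng


def apply_scaler(X: np.ndarray, mn: np.ndarray, rng: np.ndarray) -> np.ndarray:
    return -1.0 + 2.0 * (X - mn) / rng


def default_c_grid() -> list[float]:
    return [2.0 ** e for e in range(-5, 16)]


def default_g_grid() -> list[float]:
    return [2.0 ** e for e in range(-15, -4)]


@dataclass
class SvmConfig:
    c: float = DEFAULT_C
    g: float = DEFAULT_G
    grid_c: list[float] = field(default_factory=default_c_grid)
    grid_g: list[float] = field(default_factory=default_g_grid)
    cv_folds: int = 7
    seed: int = 0
    class_weight: str | None = None  # "balanced" opt-in; the default is unweighted
    scale: bool = True               # svm-scale-style [-1,1] per-feature scaling

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0:
            raise ValueError(f"c and g must be positive, got c={self.c}, g={self.g}")


@dataclass
class TrainedModel:
    """Fitted SVM plus the exact feature columns it expects."""

    feature_names: list[str]
    config: SvmConfig
    svc: SVC
    scale_min: np.ndarray | None = None
    scale_range: np.ndarray | None = None
    dataset_fingerprint: str = ""

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.scale_min is None:
            return X
        return apply_scaler(X, self.scale_min, self.scale_range)

    def _check_columns(self, matrix: FeatureMatrix) -> np.ndarray:
        if list(matrix.columns) != list(self.feature_names):
            missing = [f for f in self.feature_names if f not in set(matrix.columns)]
            extra = [f for f in matrix.columns if f not in set(self.feature_names)]
            if missing or extra:
                raise ValueError(
                    f"feature columns do not match the model: "
                    f"missing {missing[:5]}, extra {extra[:5]}"
                )
            raise ValueError(
                "feature columns are permuted relative to the model's "
                "feature_names; reorder with FeatureMatrix.select first"
            )
        return matrix.values


def _as_values(features: FeatureMatrix | np.ndarray, model: TrainedModel | None = None) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        if model is not None:
            return model._check_columns(features)
        return features.values
    X = np.asarray(features, dtype=float)
    if model is not None and X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def train_svm(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    config: SvmConfig | None = None,
) -> TrainedModel:
    """Fit the soft-margin RBF SVM; deterministic for fixed inputs."""
    config = config or SvmConfig()
    X = _as_values(features)
    y = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires samples from both classes")
    if config.scale:
        mn, rng = fit_scaler(X)
        X_fit = apply_scaler(X, mn, rng)
    else:
        mn = rng = None
        X_fit = X
    svc = SVC(C=config.c, kernel="rbf", gamma=config.g, class_weight=config.class_weight)
    svc.fit(X_fit, y)
    names = list(features.columns) if isinstance(features, FeatureMatrix) else [
        f"f{i}" for i in range(X.shape[1])
    ]
    return TrainedModel(
        feature_names=names,
        config=config,
        svc=svc,
        scale_min=mn,
        scale_range=rng,
        dataset_fingerprint=_fingerprint(X, y),
    )


def predict(model: TrainedModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Binary labels: 1 = cancerlectin, 0 = non-cancerlectin."""
    X = _as_values(features, model)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int)
    return model.svc.predict(model.transform(X)).astype(int)


def decision_values(model: TrainedModel, features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Signed scores; larger = more cancerlectin-like; sign matches predict."""
    X = _as_values(features, model)
    if X.shape[0] == 0:
        return np.empty(0, dtype=float)
    return model.svc.decision_function(model.transform(X))


def grid_search(
    features: FeatureMatrix | np.ndarray,
    labels: Sequence[int],
    config: SvmConfig | None = None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Exhaustive (c, g) search by stratified k-fold accuracy.

    Every pair is scored on the same fold split (drawn from
    ``config.seed``); ties are broken towards smaller c, then smaller g.
    Returns the best pair and the full accuracy table.
    """
    config = config or SvmConfig()
    if not config.grid_c or not config.grid_g:
        raise ValueError("grid search requires non-empty grids")
    if config.cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    X = _as_values(features)
    y = np.asarray(labels, dtype=int)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    splits = list(skf.split(X, y))

    rows = []
    for c in sorted(config.grid_c):
        for g in sorted(config.grid_g):
            correct = 0
            for train_idx, test_idx in splits:
                Xtr, Xte = X[train_idx], X[test_idx]
                if config.scale:
                    mn, rng = fit_scaler(Xtr)
                    Xtr, Xte = apply_scaler(Xtr, mn, rng), apply_scaler(Xte, mn, rng)
                clf = SVC(C=c, kernel="rbf", gamma=g, class_weight=config.class_weight)
                try:
                    clf.fit(Xtr, y[train_idx])
                except Exception as exc:  # pragma: no cover
                    raise RuntimeError(f"CV failure at (c={c}, g={g}): {exc}") from exc
                correct += int(np.sum(clf.predict(Xte) == y[test_idx]))
            rows.append({"c": c, "g": g, "cv_accuracy": correct / len(y)})
    table = pd.DataFrame(rows)
    best = table.sort_values(
        ["cv_accuracy", "c", "g"], ascending=[False, True, True]
    ).iloc[0]
    return (float(best["c"]), float(best["g"])), table


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist a self-describing archive (features, (c, g), fitted state)."""
    joblib.dump(
        {
            "format": "canlect-svm-v1",
            "feature_names": model.feature_names,
            "c": model.config.c,
            "g": model.config.g,
            "class_weight": model.config.class_weight,
            "seed": model.config.seed,
            "scale": model.config.scale,
            "scale_min": model.scale_min,
            "scale_range": model.scale_range,
            "dataset_fingerprint": model.dataset_fingerprint,
            "svc": model.svc,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    blob = joblib.load(path)
    if blob.get("format") != "canlect-svm-v1":
        raise ValueError(f"not a canlect model archive: {path}")
    config = SvmConfig(
        c=blob["c"], g=blob["g"], class_weight=blob["class_weight"],
        seed=blob["seed"], scale=blob["scale"],
    )
    return TrainedModel(
        feature_names=blob["feature_names"],
        config=config,
        svc=blob["svc"],
        scale_min=blob["scale_min"],
        scale_range=blob["scale_range"],
        dataset_fingerprint=blob["dataset_fingerprint"],
    )
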