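"""Performance assessment: Acc/Sn/Sp, k-fold CV, jackknife, ROC and AUC.

Sensitivity Sn = TP / (TP + FN) measures the ability to recognise true
cancerlectins, specificity Sp = TN / (TN + FP) the ability to recognise
non-cancerlectins, and Acc = (TP + TN) / total the overall accuracy.
The jackknife (leave-one-out) protocol predicts every sample with a
model trained on all the others; it involves no randomness, so its
report is unique for a given dataset and configuration.  ROC curves use
the standard convention — false-positive rate on the abscissa,
true-positive rate on the ordinate — with AUC by the trapezoidal rule,
which equals the Mann–Whitney concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .features import FeatureMatrix, build_matrix, count_tripeptides
from .io import LabeledDataset
from .svm import SvmConfig, decision_values, predict, train_svm


class UndefinedMetricError(ValueError):
    """A rate metric has a zero denominator (e.g. Sn with no positives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true, dtype=int)
        yp = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((yt == 1) & (yp == 1))),
            TN=int(np.sum((yt == 0) & (yp == 0))),
            FP=int(np.sum((yt == 0) & (yp == 1))),
            FN=int(np.sum((yt == 1) & (yp == 0))),
        )

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(Acc, Sn, Sp) as exact proportions; raises on a zero denominator."""
    if counts.total == 0:
        raise UndefinedMetricError("no samples")
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("no positives: sensitivity undefined")
    if counts.TN + counts.FP == 0:
        raise UndefinedMetricError("no negatives: specificity undefined")
    acc = Fraction(counts.TP + counts.TN, counts.total)
    sn = Fraction(counts.TP, counts.TP + counts.FN)
    sp = Fraction(counts.TN, counts.TN + counts.FP)
    return float(acc), float(sn), float(sp)


def roc_and_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points ((0,0) .. (1,1)) and trapezoidal AUC from signed scores.

    Thresholds sweep the distinct score values; tied scores produce
    diagonal segments (the trapezoid handles them as a group).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite decision scores")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class EvalReport:
    """Pooled confusion counts, the three rate metrics, ROC and provenance."""

    counts: ConfusionCounts
    acc: float
    sn: float
    sp: float
    roc_points: list[tuple[float, float]]
    auc: float
    protocol: str                 # resubstitution | kfold | jackknife
    folds: int | None = None
    seed: int | None = None       # None for jackknife (no random component)
    svm_c: float | None = None
    svm_g: float | None = None
    n_features: int | None = None

    def to_text(self) -> str:
        """Deterministic key/value report (no timestamps)."""
        lines = [
            f"protocol\t{self.protocol}",
            f"folds\t{'-' if self.folds is None else self.folds}",
            f"seed\t{'-' if self.seed is None else self.seed}",
            f"svm_c\t{'-' if self.svm_c is None else repr(self.svm_c)}",
            f"svm_g\t{'-' if self.svm_g is None else repr(self.svm_g)}",
            f"n_features\t{'-' if self.n_features is None else self.n_features}",
            f"TP\t{self.counts.TP}",
            f"TN\t{self.counts.TN}",
            f"FP\t{self.counts.FP}",
            f"FN\t{self.counts.FN}",
            f"Acc\t{self.acc:.6f}",
            f"Sn\t{self.sn:.6f}",
            f"Sp\t{self.sp:.6f}",
            f"AUC\t{self.auc:.6f}",
        ]
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    def save_roc_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("fpr\ttpr\n")
            for x, y in self.roc_points:
                fh.write(f"{x:.12g}\t{y:.12g}\n")


def _evaluate_folds(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    config: SvmConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
    protocol: str,
    folds: int | None,
    seed: int | None,
) -> EvalReport:
    """Shared engine: each sample predicted once by a model not trained on it."""
    pred = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(
                f"{protocol}: a training fold contains a single class "
                f"(class sizes too small)"
            )
        model = train_svm(X[train_idx], y[train_idx], config)
        pred[test_idx] = predict(model, X[test_idx])
        scores[test_idx] = decision_values(model, X[test_idx])
    counts = ConfusionCounts.from_predictions(y, pred)
    acc, sn, sp = metrics(counts)
    roc_points, auc = roc_and_auc(scores, y)
    return EvalReport(
        counts=counts,
        acc=acc,
        sn=sn,
        sp=sp,
        roc_points=roc_points,
        auc=auc,
        protocol=protocol,
        folds=folds,
        seed=seed,
        svm_c=config.c,
        svm_g=config.g,
        n_features=len(feature_names),
    )


def _evaluate_folds_nested(
    dataset: LabeledDataset,
    matrix: FeatureMatrix,
    config: SvmConfig,
    splits: list[tuple[np.ndarray, np.ndarray]],
    top_k: int,
    policy: str,
    protocol: str,
    folds: int | None,
    seed: int | None,
) -> EvalReport:
    """Unbiased variant: the CL ranking is recomputed inside every training
    fold and the top-``top_k`` features of that fold-local ranking are used,
    so no held-out label ever influences feature selection."""
    from .selection import ClassCountTable, confidence_levels

    y = dataset.labels
    per_record = np.stack(
        [count_tripeptides(rec, policy)[0] for rec in dataset.records]
    )
    pred = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    for train_idx, test_idx in splits:
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError(f"{protocol}: a training fold contains a single class")
        n = np.column_stack(
            [
                per_record[train_idx][y[train_idx] == 1].sum(axis=0),
                per_record[train_idx][y[train_idx] == 0].sum(axis=0),
            ]
        )
        ranking = confidence_levels(ClassCountTable(n=n))
        cols = ranking.order[:top_k]
        X = matrix.values[:, cols]
        model = train_svm(X[train_idx], y[train_idx], config)
        pred[test_idx] = predict(model, X[test_idx])
        scores[test_idx] = decision_values(model, X[test_idx])
    counts = ConfusionCounts.from_predictions(y, pred)
    acc, sn, sp = metrics(counts)
    roc_points, auc = roc_and_auc(scores, y)
    return EvalReport(
        counts=counts, acc=acc, sn=sn, sp=sp,
        roc_points=roc_points, auc=auc,
        protocol=f"{protocol}+nested-selection",
        folds=folds, seed=seed,
        svm_c=config.c, svm_g=config.g, n_features=top_k,
    )


def _prepare(
    dataset: LabeledDataset,
    feature_subset: Sequence[str] | None,
    policy: str,
    matrix: FeatureMatrix | None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    dataset.require_both_classes()
    if matrix is None:
        matrix = build_matrix(dataset, policy)
    if feature_subset is not None:
        matrix = matrix.select(list(feature_subset))
    return matrix.values, dataset.labels, list(matrix.columns)


def kfold_cv(
    dataset: LabeledDataset,
    feature_subset: Sequence[str] | None = None,
    config: SvmConfig | None = None,
    k: int = 7,
    seed: int = 0,
    policy: str = "strict",
    matrix: FeatureMatrix | None = None,
    nested_rank_top: int | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    With ``nested_rank_top`` set, ``feature_subset`` is ignored and the
    top-k CL features are re-selected inside every training fold.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or SvmConfig()
    if nested_rank_top is not None:
        dataset.require_both_classes()
        if matrix is None:
            matrix = build_matrix(dataset, policy)
        y = dataset.labels
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = [(tr, te) for tr, te in skf.split(matrix.values, y)]
        return _evaluate_folds_nested(
            dataset, matrix, config, splits, nested_rank_top, policy,
            "kfold", k, seed,
        )
    X, y, names = _prepare(dataset, feature_subset, policy, matrix)
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < k and k != len(y):
        raise ValueError(
            f"each class needs >= {k} members for stratified {k}-fold CV; "
            f"class sizes are {class_sizes.tolist()}"
        )
    if k == len(y):  # boundary: k = n is exactly the jackknife
        return jackknife(dataset, feature_subset, config, policy, matrix)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = [(tr, te) for tr, te in skf.split(X, y)]
    return _evaluate_folds(X, y, names, config, splits, "kfold", k, seed)


def jackknife(
    dataset: LabeledDataset,
    feature_subset: Sequence[str] | None = None,
    config: SvmConfig | None = None,
    policy: str = "strict",
    matrix: FeatureMatrix | None = None,
    nested_rank_top: int | None = None,
) -> EvalReport:
    """Leave-one-out evaluation; deterministic, no seed involved.

    ``nested_rank_top`` switches on fold-internal feature selection (the
    held-out sequence never contributes to the CL ranking that chooses
    the features used to predict it).
    """
    config = config or SvmConfig()
    if np.bincount(dataset.labels, minlength=2).min() < 2:
        raise ValueError("jackknife requires >= 2 samples per class")
    n = len(dataset)
    all_idx = np.arange(n)
    splits = [(np.delete(all_idx, i), np.asarray([i])) for i in range(n)]
    if nested_rank_top is not None:
        dataset.require_both_classes()
        if matrix is None:
            matrix = build_matrix(dataset, policy)
        return _evaluate_folds_nested(
            dataset, matrix, config, splits, nested_rank_top, policy,
            "jackknife", None, None,
        )
    X, y, names = _prepare(dataset, feature_subset, policy, matrix)
    return _evaluate_folds(X, y, names, config, splits, "jackknife", None, None)
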