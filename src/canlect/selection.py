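"""Binomial-confidence feature ranking and incremental feature selection.

The selection statistic asks, for each tripeptide i and class j, whether
its class-conditional occurrence count n_ij could plausibly arise under a
null in which each of the tripeptide's N_i total occurrences falls into
class j independently with the occurrence-weighted class prior
q_j = m_j / M (m_j = total tripeptide occurrences in class j, M = grand
total).  The upper-tail probability

    P(n_ij) = sum_{m = n_ij}^{N_i} C(N_i, m) q_j^m (1 - q_j)^{N_i - m}

is small when the tripeptide is over-represented in class j; the
confidence level is CL_ij = 1 - P(n_ij) and each tripeptide is scored by
CL_i = max_j CL_ij.  Features are then ranked by descending CL and a
subset is chosen either by a CL threshold or by incremental feature
selection (IFS): walk the ranking downward, adding one feature (or one
block of CL-tied features) at a time, and record the stratified k-fold
cross-validated accuracy of an RBF-SVM on each cumulative subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Integral

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .svm import apply_scaler, fit_scaler
from .features import N_TRIPEPTIDES, TRIPEPTIDES, FeatureMatrix, build_matrix, count_tripeptides
from .io import LabeledDataset

#: two CL values closer than this are treated as tied
CL_TIE_TOL = 1e-12


@dataclass
class ClassCountTable:
    """Raw tripeptide occurrence counts per class.

    ``n`` has shape (8000, 2): column 0 = positive class (label 1),
    column 1 = negative class (label 0).  ``N = n.sum(axis=1)`` are the
    per-tripeptide totals, ``m = n.sum(axis=0)`` the per-class totals,
    ``M = m.sum()`` the grand total and ``q = m / M`` the class priors.
    """

    n: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.n.shape != (N_TRIPEPTIDES, 2):
            raise ValueError(f"count table must be ({N_TRIPEPTIDES}, 2), got {self.n.shape}")
        if self.M == 0:
            raise ValueError("no tripeptide occurrences anywhere (M = 0)")

    @property
    def N(self) -> np.ndarray:
        return self.n.sum(axis=1)

    @property
    def m(self) -> np.ndarray:
        return self.n.sum(axis=0)

    @property
    def M(self) -> int:
        return int(self.n.sum())

    @property
    def q(self) -> np.ndarray:
        return self.m / self.M


def tabulate_counts(dataset: LabeledDataset, policy: str = "strict") -> ClassCountTable:
    """Sum raw tripeptide counts over all sequences of each class."""
    dataset.require_both_classes()
    n = np.zeros((N_TRIPEPTIDES, 2), dtype=np.int64)
    for rec, label in zip(dataset.records, dataset.labels):
        counts, _ = count_tripeptides(rec, policy)
        n[:, 0 if label == 1 else 1] += counts
    return ClassCountTable(n=n)


def binomial_tail(n: int, N: int, q: float) -> float:
    """Upper-tail binomial probability P(X >= n) for X ~ Binomial(N, q).

    Numerically stable for N up to at least 10^6 (regularised incomplete
    beta via the scipy survival function).
    """
    if not (isinstance(n, Integral) and isinstance(N, Integral)):
        raise TypeError("n and N must be integers")
    if n < 0 or n > N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"require 0 <= q <= 1, got q={q}")
    if n == 0:
        return 1.0
    return float(binom.sf(n - 1, N, q))


def _tail_array(n: np.ndarray, N: np.ndarray, q: float) -> np.ndarray:
    """Vectorised P(X >= n); exactly 1 where n == 0."""
    out = binom.sf(n - 1, N, q)
    return np.where(n == 0, 1.0, out)


@dataclass
class CLRanking:
    """Per-tripeptide tail probabilities, confidence levels and rank order.

    ``order`` lists column indices of every tripeptide with N_i > 0,
    sorted by descending CL_i, then ascending min-class tail, then
    descending N_i, then lexicographic tripeptide string — a fully
    deterministic rule.  Never-observed tripeptides are excluded from the
    ranking (their CL is vacuous) and listed in ``unobserved``.
    """

    tail: np.ndarray           # (8000, 2)
    cl: np.ndarray             # (8000, 2) = 1 - tail
    cl_max: np.ndarray         # (8000,)
    dominant_class: np.ndarray  # (8000,) 1 or 2 (class index j of the max)
    order: np.ndarray          # ranked tripeptide column indices, N_i > 0 only
    table: ClassCountTable

    @property
    def ranked_features(self) -> list[str]:
        return [TRIPEPTIDES.order[i] for i in self.order]

    @property
    def unobserved(self) -> list[str]:
        mask = self.table.N == 0
        return [TRIPEPTIDES.order[i] for i in np.flatnonzero(mask)]

    def to_frame(self) -> pd.DataFrame:
        """Ranking export: one row per ranked tripeptide."""
        idx = self.order
        return pd.DataFrame(
            {
                "tripeptide": [TRIPEPTIDES.order[i] for i in idx],
                "n_pos": self.table.n[idx, 0],
                "n_neg": self.table.n[idx, 1],
                "N": self.table.N[idx],
                "CL_pos": self.cl[idx, 0],
                "CL_neg": self.cl[idx, 1],
                "CL": self.cl_max[idx],
                "dominant_class": self.dominant_class[idx],
                "rank": np.arange(1, len(idx) + 1),
            }
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def confidence_levels(table: ClassCountTable) -> CLRanking:
    """Compute CL_ij = 1 - P(n_ij) per class, CL_i = max_j, and rank."""
    N = table.N
    q = table.q
    tail = np.column_stack([_tail_array(table.n[:, j], N, q[j]) for j in (0, 1)])
    cl = 1.0 - tail
    cl_max = cl.max(axis=1)
    dominant = np.where(cl[:, 0] >= cl[:, 1], 1, 2)
    observed = np.flatnonzero(N > 0)
    min_tail = tail.min(axis=1)
    keys = sorted(
        observed,
        key=lambda i: (-cl_max[i], min_tail[i], -N[i], TRIPEPTIDES.order[i]),
    )
    return CLRanking(
        tail=tail,
        cl=cl,
        cl_max=cl_max,
        dominant_class=dominant,
        order=np.asarray(keys, dtype=int),
        table=table,
    )


def filter_by_cl(ranking: CLRanking, threshold: float) -> list[str]:
    """All ranked tripeptides with CL strictly above ``threshold``."""
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    return [
        TRIPEPTIDES.order[i]
        for i in ranking.order
        if ranking.cl_max[i] > threshold
    ]


@dataclass
class IFSResult:
    """Accuracy-vs-subset-size curve from incremental feature selection."""

    subset_sizes: list[int]
    cv_accuracy: list[float]
    ranked_features: list[str]
    folds: int
    seed: int
    svm_c: float
    svm_g: float

    @property
    def argmax_size(self) -> int:
        """Smallest subset size attaining the maximum CV accuracy."""
        best = max(self.cv_accuracy)
        for size, acc in zip(self.subset_sizes, self.cv_accuracy):
            if acc == best:
                return size
        raise RuntimeError("empty IFS curve")

    def chosen_features(self, size: int | None = None) -> list[str]:
        """Top-``size`` features of the ranking (default: argmax size)."""
        k = self.argmax_size if size is None else size
        return self.ranked_features[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subset_size": self.subset_sizes, "cv_accuracy": self.cv_accuracy}
        )

    def save_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def _tie_groups(cl_values: np.ndarray) -> list[int]:
    """Sizes of consecutive blocks of CL-tied features in rank order."""
    groups: list[int] = []
    start = 0
    for i in range(1, len(cl_values) + 1):
        if i == len(cl_values) or abs(cl_values[i] - cl_values[start]) > CL_TIE_TOL:
            groups.append(i - start)
            start = i
    return groups


def incremental_feature_selection(
    dataset: LabeledDataset,
    ranking: CLRanking,
    folds: int = 7,
    svm_params: tuple[float, float] = (2.0 ** 11, 2.0 ** -13),
    group_ties: bool = True,
    seed: int = 0,
    policy: str = "strict",
    matrix: FeatureMatrix | None = None,
    max_size: int | None = None,
    scale: bool = True,
) -> IFSResult:
    """Walk the CL ranking downward and CV-score each cumulative subset.

    One stratified k-fold split is drawn from ``seed`` and reused at every
    subset size so the accuracy curve is comparable point to point.  With
    ``group_ties`` (the default) each step adds the whole block of
    features sharing the next CL value; ``max_size`` optionally stops the
    walk early (the full walk ends at the complete ranked-feature count).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    dataset.require_both_classes()
    counts = np.bincount(dataset.labels, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"each class needs >= {folds} members for {folds}-fold CV; "
            f"class sizes are {counts.tolist()}"
        )
    if matrix is None:
        matrix = build_matrix(dataset, policy)
    c, g = svm_params
    y = dataset.labels
    col_index = {t: i for i, t in enumerate(matrix.columns)}
    ranked = ranking.ranked_features
    ranked_cols = np.asarray([col_index[t] for t in ranked], dtype=int)
    cl_in_order = ranking.cl_max[ranking.order]

    if group_ties:
        steps = _tie_groups(cl_in_order)
    else:
        steps = [1] * len(ranked)
    sizes: list[int] = []
    total = 0
    for s in steps:
        total += s
        if max_size is not None and total >= max_size:
            sizes.append(min(total, len(ranked)))
            break
        sizes.append(total)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))

    accuracies: list[float] = []
    X_full = matrix.values[:, ranked_cols]
    for size in sizes:
        X = X_full[:, :size]
        correct = 0
        for train_idx, test_idx in splits:
            Xtr, Xte = X[train_idx], X[test_idx]
            if scale:
                mn, rng = fit_scaler(Xtr)
                Xtr, Xte = apply_scaler(Xtr, mn, rng), apply_scaler(Xte, mn, rng)
            clf = SVC(C=c, kernel="rbf", gamma=g)
            try:
                clf.fit(Xtr, y[train_idx])
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(f"CV failure at subset size {size}: {exc}") from exc
            correct += int(np.sum(clf.predict(Xte) == y[test_idx]))
        accuracies.append(correct / len(y))

    return IFSResult(
        subset_sizes=sizes,
        cv_accuracy=accuracies,
        ranked_features=ranked,
        folds=folds,
        seed=seed,
        svm_c=c,
        svm_g=g,
    )
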