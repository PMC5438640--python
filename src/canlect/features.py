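"""Tripeptide (3-mer) composition encoding.

Each protein of length L is scanned with overlapping windows of width 3
(step 1) and encoded as the normalised frequency vector over the
20^3 = 8000 possible tripeptides:

    f_i = n_i / W,

where n_i is the count of the i-th tripeptide and W is the number of
counted windows (W = L - 2 under the strict residue policy; under the
drop-invalid-windows policy, windows touching a non-standard residue are
excluded and W shrinks accordingly, which keeps the vector exactly
normalised).  Columns are ordered lexicographically over
``ACDEFGHIKLMNPQRSTVWY`` so AAA is column 0 and YYY column 7999.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    STANDARD_AA,
    LabeledDataset,
    ProteinRecord,
    SequenceValidationError,
    _check_policy,
)

N_TRIPEPTIDES = 20 ** 3  # 8000


class TripeptideIndex:
    """The fixed lexicographic tripeptide -> column mapping (8000 entries)."""

    def __init__(self) -> None:
        self.order: list[str] = [
            "".join(t) for t in itertools.product(STANDARD_AA, repeat=3)
        ]
        self.index_of: dict[str, int] = {t: i for i, t in enumerate(self.order)}

    def __len__(self) -> int:
        return N_TRIPEPTIDES

    def __getitem__(self, tripeptide: str) -> int:
        return self.index_of[tripeptide]


#: module-level shared instance; the mapping is immutable
TRIPEPTIDES = TripeptideIndex()

_AA_CODE = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(STANDARD_AA):
    _AA_CODE[ord(_a)] = _i


def _encode(sequence: str) -> np.ndarray:
    """Residues -> integer codes 0..19, -1 for non-standard."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _AA_CODE[raw]


def count_tripeptides(
    record: ProteinRecord, policy: str = "strict"
) -> tuple[np.ndarray, int]:
    """Count overlapping tripeptide windows.

    Returns ``(counts, windows)`` where ``counts`` is the length-8000
    integer vector and ``windows = counts.sum()`` is the number of valid
    windows.  Under ``drop-invalid-windows`` a window containing any
    non-standard residue is skipped.
    """
    _check_policy(policy)
    codes = _encode(record.sequence)
    if policy == "strict" and np.any(codes < 0):
        bad = sorted({record.sequence[i] for i in np.flatnonzero(codes < 0)})
        raise SequenceValidationError(
            f"record {record.id!r}: non-standard residue(s) {', '.join(bad)} "
            "under strict policy"
        )
    window_codes = codes[:-2] * 400 + codes[1:-1] * 20 + codes[2:]
    valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    window_codes = window_codes[valid]
    if window_codes.size == 0:
        raise SequenceValidationError(
            f"record {record.id!r}: zero valid tripeptide windows"
        )
    counts = np.bincount(window_codes, minlength=N_TRIPEPTIDES)
    return counts, int(window_codes.size)


def composition_vector(record: ProteinRecord, policy: str = "strict") -> np.ndarray:
    """Normalised tripeptide frequencies f_i = n_i / windows (sums to 1)."""
    counts, windows = count_tripeptides(record, policy)
    return counts / windows


@dataclass
class FeatureMatrix:
    """Per-sequence tripeptide frequency rows with named columns.

    ``columns`` is the full 8000-tripeptide order for freshly built
    matrices; :meth:`select` yields restricted matrices carrying only a
    subset (row sums then no longer equal 1).
    """

    values: np.ndarray          # (n_rows, n_cols) float
    row_ids: list[str]
    columns: list[str]
    window_counts: np.ndarray   # (n_rows,) int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.window_counts = np.asarray(self.window_counts, dtype=int)
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} ids x {len(self.columns)} columns"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select(self, feature_names: Sequence[str]) -> "FeatureMatrix":
        """Restrict to the given tripeptides, in the given order."""
        col_index = {c: i for i, c in enumerate(self.columns)}
        missing = [f for f in feature_names if f not in col_index]
        if missing:
            raise KeyError(f"unknown feature column(s): {missing[:5]}")
        idx = [col_index[f] for f in feature_names]
        return FeatureMatrix(
            values=self.values[:, idx],
            row_ids=list(self.row_ids),
            columns=list(feature_names),
            window_counts=self.window_counts.copy(),
        )

    def to_frame(self, labels: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.columns)
        df.index.name = "id"
        if labels is not None:
            df.insert(0, "label", np.asarray(labels, dtype=int))
        return df

    def save_tsv(self, path: str | Path, labels: np.ndarray | None = None) -> None:
        """Tab-separated export: id column, optional label column, one
        column per tripeptide, values at 12 significant digits."""
        self.to_frame(labels).to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def load_tsv(cls, path: str | Path) -> tuple["FeatureMatrix", np.ndarray | None]:
        df = pd.read_csv(path, sep="\t", index_col="id")
        labels = None
        if "label" in df.columns:
            labels = df.pop("label").to_numpy(dtype=int)
        values = df.to_numpy(dtype=float)
        # window counts are not serialised; reconstruct a placeholder
        return (
            cls(
                values=values,
                row_ids=[str(i) for i in df.index],
                columns=list(df.columns),
                window_counts=np.zeros(len(df), dtype=int),
            ),
            labels,
        )


def build_matrix(dataset: LabeledDataset, policy: str = "strict") -> FeatureMatrix:
    """Encode every record of a dataset; one 8000-column row per record."""
    rows = np.empty((len(dataset), N_TRIPEPTIDES), dtype=float)
    windows = np.empty(len(dataset), dtype=int)
    for k, rec in enumerate(dataset.records):
        counts, w = count_tripeptides(rec, policy)
        rows[k] = counts / w
        windows[k] = w
    return FeatureMatrix(
        values=rows,
        row_ids=dataset.ids,
        columns=list(TRIPEPTIDES.order),
        window_counts=windows,
    )
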