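"""Reading, validating and labelling protein sequences from FASTA.

Sequences are expected over the 20 standard amino acids
(``ACDEFGHIKLMNPQRSTVWY``).  Real UniProt entries occasionally contain
ambiguity codes (B, J, O, U, X, Z) or ``*``; two residue policies are
offered:

``strict``
    any non-standard residue is an error (the default — the tripeptide
    encoding assumes the 20-letter alphabet);
``drop-invalid-windows``
    the record is kept and the feature counter later excludes every
    length-3 window that touches a non-standard position, adjusting the
    frequency denominator accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

#: residue policies accepted throughout the package
POLICIES = ("strict", "drop-invalid-windows")


class SequenceValidationError(ValueError):
    """A record violates the residue alphabet or minimum-length contract."""


class DuplicateIdError(ValueError):
    """Two records share an identifier."""


class EmptyClassError(ValueError):
    """A class has no sequences after validation."""


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise ValueError(f"unknown residue policy {policy!r}; expected one of {POLICIES}")


@dataclass(frozen=True)
class ProteinRecord:
    """One identifier plus an uppercased amino-acid sequence (length >= 3)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise SequenceValidationError(
                f"record {self.id!r}: sequence shorter than 3 residues "
                f"(length {len(self.sequence)}) — no tripeptide window exists"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def invalid_positions(self) -> list[int]:
        """0-based positions holding non-standard residues."""
        return [i for i, a in enumerate(self.sequence) if a not in _STANDARD_SET]


@dataclass
class LabeledDataset:
    """Ordered records with parallel binary labels (1 = positive class)."""

    records: list[ProteinRecord]
    labels: np.ndarray
    class_names: tuple[str, str] = ("cancerlectin", "non-cancerlectin")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.records) != len(self.labels):
            raise ValueError(
                f"{len(self.records)} records but {len(self.labels)} labels"
            )
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def require_both_classes(self) -> None:
        for label, name in ((1, self.class_names[0]), (0, self.class_names[1])):
            if not np.any(self.labels == label):
                raise EmptyClassError(f"class {name!r} (label {label}) is empty")

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            records=[self.records[i] for i in idx],
            labels=self.labels[idx],
            class_names=self.class_names,
        )


def _validate_record(rec: ProteinRecord, policy: str) -> ProteinRecord:
    if policy == "strict":
        bad = rec.invalid_positions()
        if bad:
            residues = sorted({rec.sequence[i] for i in bad})
            raise SequenceValidationError(
                f"record {rec.id!r}: non-standard residue(s) "
                f"{', '.join(residues)} at position(s) {bad[:5]} under strict policy"
            )
    return rec


def read_fasta(path: str | Path, policy: str = "strict") -> list[ProteinRecord]:
    """Parse a FASTA file into validated :class:`ProteinRecord` objects.

    Records are returned in file order; sequences are uppercased and
    whitespace/line wrapping in bodies is ignored.  Duplicate identifiers
    within the file, sequences shorter than 3 residues, and (under the
    strict policy) non-standard residues are errors naming the record.
    """
    _check_policy(policy)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise DuplicateIdError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        rec = ProteinRecord(id=entry.id, sequence=str(entry.seq).upper())
        records.append(_validate_record(rec, policy))
    if not records:
        raise SequenceValidationError(f"no FASTA records found in {path}")
    return records


def load_labeled(
    positive_path: str | Path,
    negative_path: str | Path,
    policy: str = "strict",
    class_names: tuple[str, str] = ("cancerlectin", "non-cancerlectin"),
) -> LabeledDataset:
    """Load a two-class dataset: positives (label 1) first, then negatives."""
    pos = read_fasta(positive_path, policy)
    neg = read_fasta(negative_path, policy)
    dup = {r.id for r in pos} & {r.id for r in neg}
    if dup:
        raise DuplicateIdError(
            f"duplicate id(s) across classes: {sorted(dup)[:5]}"
        )
    ds = LabeledDataset(
        records=pos + neg,
        labels=np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)]),
        class_names=class_names,
    )
    ds.require_both_classes()
    return ds


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line wrapping (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
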