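"""Synthetic two-class protein corpora with planted tripeptide enrichment.

Negative sequences are i.i.d. draws from a background residue
distribution (uniform over the 20 standard amino acids by default).
Positive sequences start as the same background draws, after which a
Poisson-distributed number of planted-tripeptide copies is written over
the sequence at uniformly chosen, mutually non-overlapping positions.
Overwriting (rather than splicing) keeps sequence lengths exactly as
drawn, so the composition denominator L - 2 is controlled; overlaps
between planted copies and chance background occurrences are accepted
as realistic noise.  Everything is reproducible from the seed via
numpy's PCG64 generator.

The defaults mirror the regime the selection statistic is designed for:
two classes of 200 sequences of length 300 with 10 planted tripeptides
at an expected 10 insertions per positive sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import STANDARD_AA, LabeledDataset, ProteinRecord, write_fasta

#: fixed default motif set: 10 planted tripeptides, pairwise distinct
DEFAULT_PLANTED = (
    "ACD", "CEG", "FHI", "KLM", "NPQ",
    "RST", "VWY", "YGA", "DKC", "EMW",
)

@dataclass
class SimSpec:
    """Generator parameters; defaults are the package's standard test regime."""

    n_pos: int = 200
    n_neg: int = 200
    length_range: tuple[int, int] = (300, 300)
    background: np.ndarray | None = None     # residue probabilities, default uniform
    planted: tuple[str, ...] = DEFAULT_PLANTED
    enrichment: float = 10.0                 # expected insertions per positive sequence
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background is None:
            self.background = np.full(20, 1.0 / 20)
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 20 probabilities summing to 1")
        lo, hi = self.length_range
        if lo < 3 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        for t in self.planted:
            if len(t) != 3 or any(a not in STANDARD_AA for a in t):
                raise ValueError(f"planted tripeptide {t!r} is not a standard 3-mer")
        if self.enrichment < 0:
            raise ValueError("enrichment must be non-negative")

    def to_manifest(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "length_range": list(self.length_range),
            "background": self.background.tolist(),
            "planted": list(self.planted),
            "enrichment": self.enrichment,
            "seed": self.seed,
        }


def _background_sequence(rng: np.random.Generator, length: int, background: np.ndarray) -> list[str]:
    codes = rng.choice(20, size=length, p=background)
    return [STANDARD_AA[c] for c in codes]


def _plant(
    rng: np.random.Generator,
    residues: list[str],
    planted: tuple[str, ...],
    n_insertions: int,
) -> list[str]:
    """Overwrite n_insertions planted tripeptides at non-overlapping positions."""
    length = len(residues)
    available = set(range(length - 2))
    for _ in range(n_insertions):
        if not available:
            raise RuntimeError(
                f"could not place {n_insertions} non-overlapping tripeptides "
                f"in a sequence of length {length}"
            )
        # uniform over still-feasible starts; sorting keeps seed-reproducibility
        pos = int(rng.choice(sorted(available)))
        motif = planted[int(rng.integers(0, len(planted)))]
        residues[pos : pos + 3] = list(motif)
        available -= set(range(pos - 2, pos + 3))
    return residues


def generate(spec: SimSpec) -> LabeledDataset:
    """Draw a labelled dataset with planted enrichment in the positive class."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records: list[ProteinRecord] = []
    for k in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        residues = _background_sequence(rng, length, spec.background)
        if spec.planted and spec.enrichment > 0:
            n_ins = int(rng.poisson(spec.enrichment))
            # each placement blocks at most 5 start positions, so this cap
            # guarantees the non-overlap constraint is always satisfiable
            n_ins = min(n_ins, (length - 2) // 5)
            residues = _plant(rng, residues, spec.planted, n_ins)
        records.append(ProteinRecord(id=f"pos_{k:04d}", sequence="".join(residues)))
    for k in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        residues = _background_sequence(rng, length, spec.background)
        records.append(ProteinRecord(id=f"neg_{k:04d}", sequence="".join(residues)))
    labels = np.concatenate(
        [np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    )
    return LabeledDataset(records=records, labels=labels)


def generate_null(spec: SimSpec) -> LabeledDataset:
    """Both classes from the identical background; labels carry no signal."""
    null_spec = SimSpec(
        n_pos=spec.n_pos,
        n_neg=spec.n_neg,
        length_range=spec.length_range,
        background=spec.background,
        planted=(),
        enrichment=0.0,
        seed=spec.seed,
    )
    return generate(null_spec)


def write_dataset(
    dataset: LabeledDataset,
    pos_path: str | Path,
    neg_path: str | Path,
    manifest_path: str | Path | None = None,
    spec: SimSpec | None = None,
) -> None:
    """Standard two-FASTA export plus an optional JSON manifest."""
    pos = [r for r, y in zip(dataset.records, dataset.labels) if y == 1]
    neg = [r for r, y in zip(dataset.records, dataset.labels) if y == 0]
    write_fasta(pos, pos_path)
    write_fasta(neg, neg_path)
    if manifest_path is not None and spec is not None:
        Path(manifest_path).write_text(json.dumps(spec.to_manifest(), indent=2) + "\n")
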