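import numpy as np
import pytest

import canlect as cl


@pytest.fixture
def tiny_records():
    return [
        cl.ProteinRecord("p1", "ACDEFGHIKL"),
        cl.ProteinRecord("p2", "MNPQRSTVWY"),
        cl.ProteinRecord("p3", "AAAACCCC"),
    ]


@pytest.fixture
def toy_dataset():
    """2 positives + 3 negatives, all valid, handmade."""
    records = [
        cl.ProteinRecord("pos1", "ACDACDACD"),
        cl.ProteinRecord("pos2", "ACDEACDE"),
        cl.ProteinRecord("neg1", "WYWYWYWY"),
        cl.ProteinRecord("neg2", "KLMKLMKLM"),
        cl.ProteinRecord("neg3", "GHGHGHGH"),
    ]
    return cl.LabeledDataset(records=records, labels=np.array([1, 1, 0, 0, 0]))


@pytest.fixture(scope="session")
def small_enriched():
    """Separable two-class corpus, small enough for fast SVM work."""
    spec = cl.SimSpec(n_pos=30, n_neg=30, length_range=(100, 100),
                      enrichment=8.0, seed=7)
    return cl.generate(spec), spec


@pytest.fixture(scope="session")
def small_null():
    spec = cl.SimSpec(n_pos=30, n_neg=30, length_range=(100, 100), seed=11)
    return cl.generate_null(spec)


@pytest.fixture
def fasta_pair(tmp_path, small_enriched):
    """The small enriched corpus written out as a positive/negative FASTA pair."""
    ds, spec = small_enriched
    pos = tmp_path / "pos.fasta"
    neg = tmp_path / "neg.fasta"
    cl.write_dataset(ds, pos, neg)
    return pos, neg


def random_protein(rng, length):
    return "".join(rng.choice(list(cl.STANDARD_AA), size=length))
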