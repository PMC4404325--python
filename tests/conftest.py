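import numpy as np
import pytest

from barcodegap.alignment_io import Alignment, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def write_fasta(tmp_path):
    """Write records to a temp FASTA file and return its path."""

    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


def make_alignment(seqs, prefix="s"):
    return Alignment(
        tuple(
            SequenceRecord(f"{prefix}{i + 1}", s) for i, s in enumerate(seqs)
        )
    )


@pytest.fixture
def random_pair():
    """Factory for random sequence pairs with a controlled divergence."""

    def _make(rng, length=600, n_sub=None, ts_fraction=0.5):
        bases = "ACGT"
        transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
        a = "".join(rng.choice(list(bases), length))
        b = list(a)
        if n_sub is None:
            n_sub = int(rng.integers(1, length // 4))
        for pos in rng.choice(length, size=n_sub, replace=False):
            if rng.random() < ts_fraction:
                b[pos] = transition[a[pos]]
            else:
                b[pos] = rng.choice(
                    [c for c in bases if c != a[pos] and c != transition[a[pos]]]
                )
        return a, "".join(b)

    return _make
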