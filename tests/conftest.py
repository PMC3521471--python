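import numpy as np
import pytest

from solcard.seq_io import INSOLUBLE, SOLUBLE, LabeledDataset, ProteinSequence


def make_dataset(soluble, insoluble, prefix=("s", "i")):
    """Build a LabeledDataset from two lists of residue strings."""
    entries = [
        (ProteinSequence(f"{prefix[0]}{k}", seq), SOLUBLE) for k, seq in enumerate(soluble)
    ] + [
        (ProteinSequence(f"{prefix[1]}{k}", seq), INSOLUBLE) for k, seq in enumerate(insoluble)
    ]
    return LabeledDataset(entries)


def random_sequences(rng, n, min_len=10, max_len=60):
    """Random standard-alphabet residue strings."""
    from solcard.seq_io import STANDARD_RESIDUES

    out = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        out.append("".join(rng.choice(list(STANDARD_RESIDUES), size=length)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_dataset():
    """Two tiny classes with an obvious dipeptide split (AA-rich vs CC-rich)."""
    return make_dataset(["AAAK", "AAKA", "KAAA"], ["CCCK", "CCKC", "KCCC"])


@pytest.fixture
def fasta_file(tmp_path):
    def write(name, records):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return write
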