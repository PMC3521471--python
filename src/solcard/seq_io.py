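"""FASTA input, labeled two-class datasets, and reproducible splits.

Sequences use the 20 standard one-letter amino-acid codes. Records carrying
non-standard residues (B, J, O, U, X, Z, ``*`` or anything else) are, by
default, dropped with a warning — a library analogue of the usual curation
step that removes unknown-residue sequences — or rejected outright in strict
mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "STANDARD_RESIDUES",
    "SOLUBLE",
    "INSOLUBLE",
    "ProteinSequence",
    "LabeledDataset",
    "LoadReport",
    "read_fasta",
    "write_fasta",
    "load_labeled_dataset",
    "split_dataset",
    "kfold_partition",
]

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_RESIDUES)

SOLUBLE = "soluble"
INSOLUBLE = "insoluble"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain over the 20 standard residues; length >= 2."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError(
                f"sequence {self.id!r} shorter than 2 residues"
            )
        bad = set(self.residues) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LoadReport:
    """Counts from one FASTA load: records kept vs dropped."""

    kept: int = 0
    dropped: int = 0
    dropped_ids: list[str] = field(default_factory=list)


def read_fasta(
    path,
    policy: Literal["drop", "strict"] = "drop",
    report: LoadReport | None = None,
) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records, in file order.

    Parsing is case-insensitive (residues are upper-cased). Records with
    non-standard residues, or shorter than two residues, are dropped with a
    logged warning under ``policy="drop"`` and raise under ``policy="strict"``.
    Pass a :class:`LoadReport` to collect kept/dropped counts.
    """
    if policy not in ("drop", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    if report is None:
        report = LoadReport()
    out: list[ProteinSequence] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        try:
            out.append(ProteinSequence(record.id, str(record.seq).upper()))
            report.kept += 1
        except ValueError:
            if policy == "strict":
                raise
            report.dropped += 1
            report.dropped_ids.append(record.id)
            logger.warning("dropped record %r (non-standard residues or too short)", record.id)
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {path}")
    logger.info("loaded %s: kept %d, dropped %d", path, report.kept, report.dropped)
    return out


def write_fasta(path, seqs: Iterable[ProteinSequence], width: int = 60) -> None:
    """Write sequences as wrapped multi-record FASTA."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


@dataclass
class LabeledDataset:
    """Sequences with binary solubility labels; ids unique within the dataset."""

    entries: list[tuple[ProteinSequence, str]]

    def __post_init__(self) -> None:
        ids = [s.id for s, _ in self.entries]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate sequence id {dup!r} in dataset")
        for _, lab in self.entries:
            if lab not in (SOLUBLE, INSOLUBLE):
                raise ValueError(f"unknown label {lab!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[ProteinSequence, str]]:
        return iter(self.entries)

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [s for s, _ in self.entries]

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.entries]

    def subset(self, label: str) -> list[ProteinSequence]:
        return [s for s, lab in self.entries if lab == label]

    @property
    def n_soluble(self) -> int:
        return sum(lab == SOLUBLE for _, lab in self.entries)

    @property
    def n_insoluble(self) -> int:
        return len(self.entries) - self.n_soluble

    def require_both_classes(self) -> None:
        if self.n_soluble == 0 or self.n_insoluble == 0:
            raise ValueError("dataset must contain both soluble and insoluble sequences")

    def to_arrays(self) -> tuple[list[str], np.ndarray]:
        """Residue strings and a 0/1 label vector (1 = soluble)."""
        y = np.array([lab == SOLUBLE for _, lab in self.entries], dtype=int)
        return [s.residues for s, _ in self.entries], y


def load_labeled_dataset(
    soluble_path,
    insoluble_path,
    policy: Literal["drop", "strict"] = "drop",
) -> LabeledDataset:
    """Assemble a two-class dataset from a soluble and an insoluble FASTA file.

    Duplicate ids across the two files are rejected, as is an empty class.
    """
    sol = read_fasta(soluble_path, policy=policy)
    ins = read_fasta(insoluble_path, policy=policy)
    if not sol:
        raise ValueError(f"soluble class empty after filtering: {soluble_path}")
    if not ins:
        raise ValueError(f"insoluble class empty after filtering: {insoluble_path}")
    entries = [(s, SOLUBLE) for s in sol] + [(s, INSOLUBLE) for s in ins]
    return LabeledDataset(entries)


def _train_count(n: int, fraction: float) -> int:
    # round half-up on the per-class train count
    return int(np.floor(n * fraction + 0.5))


def split_dataset(
    ds: LabeledDataset, train_fraction: float, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified train/test split, deterministic under ``seed``.

    Per-class train counts are rounded half-up, e.g. a 0.8 fraction on class
    sizes (285, 672) yields train sizes (228, 538). (Published corpora of this
    kind were often split without stratification — e.g. a 766/191 split of 957
    sequences with class sizes 219/547 in train — which this rule does not and
    cannot reproduce; the split here is stratified by construction.)
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    ds.require_both_classes()
    rng = np.random.default_rng(seed)
    train: list[tuple[ProteinSequence, str]] = []
    test: list[tuple[ProteinSequence, str]] = []
    for label in (SOLUBLE, INSOLUBLE):
        members = [(s, label) for s in ds.subset(label)]
        if len(members) < 2:
            raise ValueError(f"class {label!r} has fewer than 2 members")
        order = rng.permutation(len(members))
        n_train = _train_count(len(members), train_fraction)
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return LabeledDataset(train), LabeledDataset(test)


def kfold_partition(
    ds: LabeledDataset, k: int, seed: int
) -> list[tuple[LabeledDataset, LabeledDataset]]:
    """Stratified k-fold partition: k (train, validation) dataset pairs.

    Every sequence appears in exactly one validation fold; per-fold class
    proportions differ from the global ones by at most one sequence per class.
    Deterministic under ``seed``.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    ds.require_both_classes()
    if min(ds.n_soluble, ds.n_insoluble) < k:
        raise ValueError("k exceeds the size of the smaller class")
    y = [lab for _, lab in ds.entries]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        folds.append(
            (
                LabeledDataset([ds.entries[i] for i in train_idx]),
                LabeledDataset([ds.entries[i] for i in val_idx]),
            )
        )
    return folds
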