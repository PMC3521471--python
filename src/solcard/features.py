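"""Dipeptide composition features and residue-level score derivation.

A sequence of length L is described by its L-1 overlapping dipeptide windows.
The 400 dipeptides are indexed first-residue-major, both positions running
alphabetically over ACDEFGHIKLMNPQRSTVWY, so index(d) = 20*i(d[0]) + i(d[1]).
This order is fixed: score-card files and composition tables written by one
installation are readable by any other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .seq_io import STANDARD_RESIDUES, ProteinSequence

if TYPE_CHECKING:  # pragma: no cover
    from .scorecard import ScoreCard

__all__ = [
    "DIPEPTIDES",
    "N_DIPEPTIDES",
    "dipeptide_index",
    "dipeptide_composition",
    "composition_matrix",
    "ClassCounts",
    "class_dipeptide_counts",
    "amino_acid_scores",
]

N_RESIDUES = 20
N_DIPEPTIDES = 400

_RESIDUE_INDEX = {r: i for i, r in enumerate(STANDARD_RESIDUES)}

#: the 400 dipeptides in canonical (first-residue-major) order
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES
)


def dipeptide_index(dipeptide: str) -> int:
    """Canonical index of a two-residue string."""
    if len(dipeptide) != 2:
        raise ValueError(f"not a dipeptide: {dipeptide!r}")
    return N_RESIDUES * _RESIDUE_INDEX[dipeptide[0]] + _RESIDUE_INDEX[dipeptide[1]]


def _residue_codes(residues: str) -> np.ndarray:
    return np.fromiter((_RESIDUE_INDEX[r] for r in residues), dtype=np.intp, count=len(residues))


def _window_counts(residues: str) -> np.ndarray:
    codes = _residue_codes(residues)
    idx = N_RESIDUES * codes[:-1] + codes[1:]
    return np.bincount(idx, minlength=N_DIPEPTIDES).astype(np.int64)


def dipeptide_composition(seq: ProteinSequence | str) -> np.ndarray:
    """Dipeptide composition vector ``w`` of a sequence.

    ``w[i] = count(dipeptide i) / (L - 1)`` over overlapping windows; the 400
    weights are nonnegative and sum to 1 for any sequence of length >= 2.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(residues) < 2:
        raise ValueError("sequence must have length >= 2")
    counts = _window_counts(residues)
    return counts / counts.sum()


def composition_matrix(seqs: Iterable[ProteinSequence | str]) -> np.ndarray:
    """Stack per-sequence compositions into an (n, 400) array."""
    rows = [dipeptide_composition(s) for s in seqs]
    if not rows:
        raise ValueError("no sequences given")
    return np.vstack(rows)


@dataclass(frozen=True)
class ClassCounts:
    """Pooled dipeptide counts for one class of sequences."""

    counts: np.ndarray  # 400 nonnegative ints
    total: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.total:
            raise ValueError("total must equal the sum of counts")

    @property
    def composition(self) -> np.ndarray:
        """Class-level dipeptide composition: counts / total."""
        if self.total == 0:
            raise ValueError("class has zero dipeptides")
        return self.counts / self.total


def class_dipeptide_counts(seqs: Sequence[ProteinSequence | str]) -> ClassCounts:
    """Pool overlapping-window dipeptide counts over a class of sequences.

    The class total is sum_j (L_j - 1).
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence list")
    counts = np.zeros(N_DIPEPTIDES, dtype=np.int64)
    for s in seqs:
        residues = s.residues if isinstance(s, ProteinSequence) else s
        if len(residues) < 2:
            raise ValueError("every sequence must have length >= 2")
        counts += _window_counts(residues)
    return ClassCounts(counts=counts, total=int(counts.sum()))


def amino_acid_scores(card: "ScoreCard | np.ndarray") -> np.ndarray:
    """Per-residue scores derived from a dipeptide card by AX/XA averaging.

    The score of residue A is the mean of the 40 values {S(AX)} u {S(XA)},
    X ranging over all 20 residues; S(AA) appears in both sets and therefore
    contributes twice. Returned in alphabetical residue order.
    """
    scores = np.asarray(getattr(card, "scores", card), dtype=float)
    if scores.shape != (N_DIPEPTIDES,):
        raise ValueError("card must provide 400 dipeptide scores")
    m = scores.reshape(N_RESIDUES, N_RESIDUES)
    return (m.sum(axis=1) + m.sum(axis=0)) / (2 * N_RESIDUES)
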