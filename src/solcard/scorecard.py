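"""The dipeptide scoring card: construction, scoring, thresholds, file I/O.

The card holds 400 per-dipeptide propensity scores in [0, 1000] and an
optional decision threshold. The initial card is purely statistical: the
difference between the soluble-class and insoluble-class dipeptide
compositions, min-max rescaled to [0, 1000]. A sequence's solubility score is
the weighted sum of card scores with its dipeptide-composition weights, and
the classification rule is "score strictly greater than threshold means
soluble" (a score exactly at the threshold is called insoluble).

Scores are kept as floats internally; reports round to integers where the
conventional presentation does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .features import (
    DIPEPTIDES,
    N_DIPEPTIDES,
    N_RESIDUES,
    class_dipeptide_counts,
    dipeptide_composition,
)
from .seq_io import INSOLUBLE, SOLUBLE, LabeledDataset, ProteinSequence

__all__ = [
    "DegenerateDataError",
    "ScoreCard",
    "raw_propensities",
    "normalize_scores",
    "build_initial_ssm",
    "solubility_score",
    "select_threshold",
    "predict",
    "predict_with_uncertainty",
    "ABSTAIN",
    "save_scorecard",
    "load_scorecard",
    "heatmap_matrix",
]

ABSTAIN = "abstain"


class DegenerateDataError(ValueError):
    """Raised when the data admit no informative card (e.g. all-equal raw scores)."""


@dataclass
class ScoreCard:
    """400 dipeptide scores in [0, 1000] plus an optional decision threshold."""

    scores: np.ndarray
    threshold: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (N_DIPEPTIDES,):
            raise ValueError("a score card holds exactly 400 dipeptide scores")
        if self.scores.min() < -1e-9 or self.scores.max() > 1000 + 1e-9:
            raise ValueError("card scores must lie in [0, 1000]")

    def score_of(self, dipeptide: str) -> float:
        from .features import dipeptide_index

        return float(self.scores[dipeptide_index(dipeptide)])

    def require_threshold(self) -> float:
        if self.threshold is None:
            raise ValueError("score card has no threshold; train one first")
        return float(self.threshold)


def raw_propensities(
    counts_soluble: np.ndarray | Sequence[float],
    total_soluble: int,
    counts_insoluble: np.ndarray | Sequence[float],
    total_insoluble: int,
) -> np.ndarray:
    """Raw per-dipeptide propensities from class counts.

    For each dipeptide: soluble-class composition minus insoluble-class
    composition, ``count_sol/total_sol - count_ins/total_ins``. These raw
    differences are what :func:`normalize_scores` maps onto [0, 1000].
    """
    if total_soluble <= 0 or total_insoluble <= 0:
        raise ValueError("class dipeptide totals must be positive")
    cs = np.asarray(counts_soluble, dtype=float)
    ci = np.asarray(counts_insoluble, dtype=float)
    return cs / total_soluble - ci / total_insoluble


def normalize_scores(raw: np.ndarray | Sequence[float]) -> np.ndarray:
    """Linear min-max rescaling of raw propensities onto [0, 1000].

    Raises if all raw values are equal: a constant card carries no signal and
    its rescaling would be arbitrary.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        raise DegenerateDataError("all raw scores equal; card would be uninformative")
    s = 1000.0 * (raw - lo) / (hi - lo)
    # the extremes are 0 and 1000 by construction; pin them against round-off
    s[raw == lo] = 0.0
    s[raw == hi] = 1000.0
    return s


def build_initial_ssm(train: LabeledDataset) -> ScoreCard:
    """Build the initial statistical scoring card from a labeled training set.

    Pools dipeptide counts per class, forms the composition difference
    (soluble minus insoluble) and min-max rescales it to [0, 1000]. The
    returned card has no threshold; fit one with :func:`select_threshold`.
    """
    train.require_both_classes()
    sol = class_dipeptide_counts(train.subset(SOLUBLE))
    ins = class_dipeptide_counts(train.subset(INSOLUBLE))
    raw = raw_propensities(sol.counts, sol.total, ins.counts, ins.total)
    return ScoreCard(
        scores=normalize_scores(raw),
        threshold=None,
        provenance={"kind": "initial", "n_soluble": train.n_soluble, "n_insoluble": train.n_insoluble},
    )


def solubility_score(seq: ProteinSequence | str, card: ScoreCard) -> float:
    """Weighted-sum solubility score: composition weights times card scores."""
    return float(dipeptide_composition(seq) @ card.scores)


def select_threshold(
    scores: Sequence[float] | np.ndarray, labels: Sequence[str] | np.ndarray
) -> tuple[float, float]:
    """Accuracy-maximizing cut-point for the rule "score > t => soluble".

    Candidates are the midpoints between consecutive distinct sorted scores
    plus one sentinel below the minimum and one above the maximum; among
    equally accurate candidates the smallest is returned. Labels may be the
    string labels or a 0/1 vector (1 = soluble).
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if s.size < 2:
        raise ValueError("need at least 2 observations to place a threshold")

    distinct = np.unique(s)
    candidates = np.concatenate(
        ([distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0])
    )
    # accuracy of "s > t" against y, vectorized over candidates
    pred = s[None, :] > candidates[:, None]
    acc = (pred == (y[None, :] == 1)).mean(axis=1)
    best = int(np.argmax(acc))  # argmax takes the first, i.e. smallest, candidate
    return float(candidates[best]), float(acc[best])


def _as_binary(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return np.array([1 if lab == SOLUBLE else 0 for lab in arr], dtype=int)
    return arr.astype(int)


def predict(seq: ProteinSequence | str, card: ScoreCard) -> str:
    """Classify a sequence: soluble iff its score strictly exceeds the threshold."""
    t = card.require_threshold()
    return SOLUBLE if solubility_score(seq, card) > t else INSOLUBLE


def predict_with_uncertainty(
    seq: ProteinSequence | str, card: ScoreCard, region_size: float
) -> str:
    """Classify with abstention inside a band of full width ``region_size``.

    A score within ``region_size / 2`` of the threshold (inclusive) yields
    :data:`ABSTAIN`; outside the band the plain rule applies.
    """
    if region_size < 0:
        raise ValueError("region_size must be nonnegative")
    t = card.require_threshold()
    s = solubility_score(seq, card)
    if abs(s - t) <= region_size / 2.0:
        return ABSTAIN
    return SOLUBLE if s > t else INSOLUBLE


# -- file formats -----------------------------------------------------------
#
# Score-card file: '#'-prefixed header lines (threshold, provenance), then
# 400 tab-separated (dipeptide, score) rows in canonical order. Scores are
# written with repr-level precision so a save/load round-trip is bit-exact.


def save_scorecard(card: ScoreCard, path) -> None:
    with open(path, "w") as fh:
        if card.threshold is not None:
            fh.write(f"# threshold\t{float(card.threshold)!r}\n")
        for key, val in sorted(card.provenance.items()):
            fh.write(f"# {key}\t{val}\n")
        fh.write("dipeptide\tscore\n")
        for dp, s in zip(DIPEPTIDES, card.scores):
            fh.write(f"{dp}\t{float(s)!r}\n")


def load_scorecard(path) -> ScoreCard:
    threshold: float | None = None
    provenance: dict = {}
    scores = np.full(N_DIPEPTIDES, np.nan)
    from .features import dipeptide_index

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "dipeptide\tscore":
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                if key == "threshold":
                    threshold = float(val)
                else:
                    provenance[key] = val
                continue
            dp, _, val = line.partition("\t")
            scores[dipeptide_index(dp)] = float(val)
    if np.isnan(scores).any():
        missing = int(np.isnan(scores).sum())
        raise ValueError(f"score-card file incomplete: {missing} dipeptides missing")
    return ScoreCard(scores=scores, threshold=threshold, provenance=provenance)


def heatmap_matrix(card: ScoreCard) -> "pd.DataFrame":
    """Card scores as a 20x20 table (rows: first residue, columns: second)."""
    import pandas as pd

    from .seq_io import STANDARD_RESIDUES

    m = card.scores.reshape(N_RESIDUES, N_RESIDUES)
    idx = list(STANDARD_RESIDUES)
    return pd.DataFrame(m, index=idx, columns=idx)
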