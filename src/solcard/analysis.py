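"""Propensity analyses built on a trained score card.

Covers dipeptide ranking, correlation of derived amino-acid scores against
physicochemical property scales (AAindex-style, 20 values per property, NA
allowed), group summaries by keyword, per-class score histograms, the
accuracy-versus-abstention curve, and positional score profiles along a
sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import DIPEPTIDES, N_DIPEPTIDES
from .metrics import pearson_r
from .scorecard import ScoreCard
from .seq_io import SOLUBLE, STANDARD_RESIDUES, ProteinSequence

__all__ = [
    "PropertyVector",
    "read_property_table",
    "SKIPPED",
    "rank_dipeptides",
    "property_correlation",
    "property_group_summary",
    "score_histogram",
    "uncertainty_accuracy_curve",
    "positional_score_profile",
]

#: marker returned for properties that cannot be correlated (NA entries)
SKIPPED = "skipped:NA"


@dataclass(frozen=True)
class PropertyVector:
    """One named per-residue property scale (alphabetical residue order).

    Missing entries are NaN; a property with any NaN is skipped by the
    correlation analyses rather than imputed.
    """

    id: str
    description: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError(f"property {self.id!r} must have exactly 20 values")

    @property
    def has_na(self) -> bool:
        return any(math.isnan(v) for v in self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def read_property_table(path) -> list[PropertyVector]:
    """Read a flat property table: id, description, then 20 values per row.

    Tab-delimited; the token ``NA`` (any case) marks a missing value. Lines
    starting with '#' and blank lines are ignored.
    """
    out: list[PropertyVector] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 22:
                raise ValueError(
                    f"property row needs 22 tab-separated fields, got {len(parts)}"
                )
            vals = tuple(
                float("nan") if p.strip().upper() == "NA" else float(p) for p in parts[2:]
            )
            out.append(PropertyVector(id=parts[0], description=parts[1], values=vals))
    return out


def rank_dipeptides(
    card: ScoreCard, top_n: int = N_DIPEPTIDES, ascending: bool = False
) -> list[tuple[str, float]]:
    """Dipeptides ranked by score, ties broken alphabetically.

    Descending by default (the high-propensity end); ``ascending=True`` gives
    the low-propensity end.
    """
    if not 0 <= top_n <= N_DIPEPTIDES:
        raise ValueError("top_n must lie in [0, 400]")
    sign = 1.0 if ascending else -1.0
    order = sorted(range(N_DIPEPTIDES), key=lambda i: (sign * card.scores[i], DIPEPTIDES[i]))
    return [(DIPEPTIDES[i], float(card.scores[i])) for i in order[:top_n]]


def property_correlation(aa_scores: np.ndarray, prop: PropertyVector) -> float | str:
    """Pearson R between derived amino-acid scores and one property scale.

    Properties with any NA value are skipped (returns :data:`SKIPPED`).
    """
    if prop.has_na:
        return SKIPPED
    return pearson_r(np.asarray(aa_scores, dtype=float), prop.as_array())


def property_group_summary(
    aa_scores: np.ndarray, props: Sequence[PropertyVector], keyword: str
) -> dict:
    """Correlation summary over all properties matching a keyword.

    Matching is a case-insensitive substring test on the description.
    NA-containing properties are excluded. Returns count, max, mean, min and
    (population) variance of the R values plus the per-property breakdown.
    """
    kw = keyword.lower()
    rs: list[tuple[str, float]] = []
    for p in props:
        if kw not in p.description.lower():
            continue
        r = property_correlation(aa_scores, p)
        if r == SKIPPED:
            continue
        rs.append((p.id, float(r)))
    if not rs:
        raise ValueError(f"no non-NA property matches keyword {keyword!r}")
    values = np.array([r for _, r in rs])
    return {
        "keyword": keyword,
        "count": len(rs),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "min": float(values.min()),
        "var": float(values.var()),
        "per_property": rs,
    }


def score_histogram(
    scores: Sequence[float] | np.ndarray,
    labels,
    bin_width: float = 50.0,
) -> dict[str, np.ndarray]:
    """Per-class binned counts of solubility scores on aligned [0, 1000] bins.

    Bins are half-open [lo, hi) with the last bin closed, so every score in
    [0, 1000] lands in exactly one bin and per-class totals are conserved.
    Returns {"edges": bin edges, "<label>": counts per class}.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("no scores given")
    edges = np.arange(0.0, 1000.0 + bin_width, bin_width)
    if edges[-1] < 1000.0:
        edges = np.append(edges, 1000.0)
    out: dict[str, np.ndarray] = {"edges": edges}
    for lab in np.unique(labels):
        counts, _ = np.histogram(scores[labels == lab], bins=edges)
        out[str(lab)] = counts
    return out


def uncertainty_accuracy_curve(
    scores: Sequence[float] | np.ndarray,
    labels,
    threshold: float,
    region_sizes: Sequence[float],
) -> list[tuple[float, float, float]]:
    """Accuracy on the classified subset for growing abstention bands.

    For each region size (full band width), sequences whose score lies within
    size/2 of the threshold are abstained; accuracy is computed on the rest.
    Returns (size, coverage, accuracy) triples; accuracy is NaN at coverage 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == SOLUBLE else 0 for lab in np.asarray(labels)]) \
        if np.asarray(labels).dtype.kind in "USO" else np.asarray(labels, dtype=int)
    out = []
    for size in region_sizes:
        if size < 0:
            raise ValueError("region sizes must be nonnegative")
        keep = np.abs(scores - threshold) > size / 2.0
        coverage = float(keep.mean())
        if keep.any():
            pred = (scores[keep] > threshold).astype(int)
            accuracy = float((pred == y[keep]).mean())
        else:
            accuracy = float("nan")
        out.append((float(size), coverage, accuracy))
    return out


def positional_score_profile(
    seq: ProteinSequence | str, card: ScoreCard
) -> list[tuple[int, str, float]]:
    """Score of each overlapping dipeptide window along a sequence.

    Positions are 1-based indices of the window's first residue; a length-L
    sequence yields L-1 entries. The unweighted mean of the profile scores
    equals the sequence's solubility score exactly.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    if len(residues) < 2:
        raise ValueError("sequence must have length >= 2")
    out = []
    for pos in range(len(residues) - 1):
        dp = residues[pos : pos + 2]
        out.append((pos + 1, dp, card.score_of(dp)))
    return out
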