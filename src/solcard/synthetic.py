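"""Synthetic two-class sequence sets with planted dipeptide propensities.

The generator emulates the structure the scoring-card method exploits: two
sequence classes whose dipeptide usage is biased in opposite directions by a
planted per-dipeptide propensity vector. Sequences are drawn from a
first-order Markov chain over residues — the soluble-class transition weight
for dipeptide d = (current, next) is proportional to
``exp(+effect_size * propensity(d))`` and the insoluble-class weight to
``exp(-effect_size * propensity(d))`` — so dipeptide structure is genuinely
plantable, unlike i.i.d. residue sampling. At ``effect_size = 0`` the two
classes are exchangeable.

Defaults (lengths 100-300, effect size 1.0, uniform base residue usage) are
the generator's standard study conditions; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .features import N_DIPEPTIDES, N_RESIDUES, class_dipeptide_counts
from .scorecard import ScoreCard
from .seq_io import INSOLUBLE, SOLUBLE, STANDARD_RESIDUES, LabeledDataset, ProteinSequence

__all__ = ["PlantedModel", "random_planted_model", "generate_planted_dataset", "recovery_report"]


@dataclass
class PlantedModel:
    """A planted propensity structure for synthetic data.

    ``propensity`` holds 400 log-odds-like per-dipeptide biases (canonical
    dipeptide order); ``effect_size`` scales how strongly the two classes are
    pushed apart (0 makes them exchangeable).
    """

    propensity: np.ndarray
    length_range: tuple[int, int] = (100, 300)
    effect_size: float = 1.0
    seed: int = 0
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    )

    def __post_init__(self) -> None:
        self.propensity = np.asarray(self.propensity, dtype=float)
        if self.propensity.shape != (N_DIPEPTIDES,):
            raise ValueError("propensity must hold 400 values")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        self.base_frequencies = np.asarray(self.base_frequencies, dtype=float)
        if self.base_frequencies.shape != (N_RESIDUES,) or (self.base_frequencies <= 0).any():
            raise ValueError("base_frequencies must be 20 positive values")
        self.base_frequencies = self.base_frequencies / self.base_frequencies.sum()


def random_planted_model(
    seed: int = 0,
    scale: float = 1.0,
    length_range: tuple[int, int] = (100, 300),
    effect_size: float = 1.0,
) -> PlantedModel:
    """A model with standard-normal (times ``scale``) planted propensities."""
    rng = np.random.default_rng(seed)
    return PlantedModel(
        propensity=rng.normal(0.0, scale, N_DIPEPTIDES),
        length_range=length_range,
        effect_size=effect_size,
        seed=seed,
    )


def _transition_matrix(model: PlantedModel, sign: float) -> np.ndarray:
    logits = sign * model.effect_size * model.propensity.reshape(N_RESIDUES, N_RESIDUES)
    weights = np.exp(logits) * model.base_frequencies[None, :]
    return weights / weights.sum(axis=1, keepdims=True)


def _sample_class(
    n: int, model: PlantedModel, sign: float, prefix: str, rng: np.random.Generator
) -> list[ProteinSequence]:
    trans = _transition_matrix(model, sign)
    cum = np.cumsum(trans, axis=1)
    lo, hi = model.length_range
    residues = np.frombuffer(STANDARD_RESIDUES.encode(), dtype="S1").astype("U1")
    seqs = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        codes = np.empty(length, dtype=np.intp)
        codes[0] = rng.choice(N_RESIDUES, p=model.base_frequencies)
        u = rng.random(length - 1)
        for pos in range(1, length):
            codes[pos] = np.searchsorted(cum[codes[pos - 1]], u[pos - 1], side="right")
        seqs.append(ProteinSequence(id=f"{prefix}{i:04d}", residues="".join(residues[codes])))
    return seqs


def generate_planted_dataset(n_sol: int, n_ins: int, model: PlantedModel) -> LabeledDataset:
    """Generate a labeled two-class dataset from a planted model.

    Deterministic under ``model.seed``; class sizes are exact.
    """
    if n_sol < 1 or n_ins < 1:
        raise ValueError("both classes need at least one sequence")
    rng = np.random.default_rng(model.seed)
    sol = _sample_class(n_sol, model, +1.0, "sol", rng)
    ins = _sample_class(n_ins, model, -1.0, "ins", rng)
    return LabeledDataset([(s, SOLUBLE) for s in sol] + [(s, INSOLUBLE) for s in ins])


def recovery_report(
    model: PlantedModel,
    card: ScoreCard,
    dataset: LabeledDataset | None = None,
    min_count: int = 5,
) -> float:
    """Spearman rank correlation between planted propensities and a learned card.

    If ``dataset`` is given (the data the card was learned from), the
    comparison is restricted to dipeptides observed at least ``min_count``
    times in it — the learned score of a never-seen dipeptide is an artifact
    of normalization, not signal. Without a dataset all 400 dipeptides enter.
    """
    mask = np.ones(N_DIPEPTIDES, dtype=bool)
    if dataset is not None:
        pooled = class_dipeptide_counts(dataset.sequences)
        mask = pooled.counts >= min_count
    if mask.sum() < 10:
        raise ValueError("too few observed dipeptides for a rank correlation")
    rho = stats.spearmanr(model.propensity[mask], card.scores[mask]).statistic
    return float(rho)
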