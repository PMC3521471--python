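"""Scikit-learn style estimators wrapping the scoring-card method.

`DipeptideComposition` turns sequences into the 400-column composition matrix
(analogous to a fixed-vocabulary CountVectorizer), and `ScoreCardClassifier`
is the full method as a fit/predict classifier: fit builds the statistical
card (optionally GA-optimized) and learns the decision threshold; predict
applies the strict "score above threshold" rule. Both compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import iga as _iga
from .features import DIPEPTIDES, amino_acid_scores, composition_matrix
from .scorecard import (
    ScoreCard,
    build_initial_ssm,
    select_threshold,
)
from .seq_io import INSOLUBLE, SOLUBLE, LabeledDataset, ProteinSequence

__all__ = ["DipeptideComposition", "ScoreCardClassifier"]


def _residue_strings(X) -> list[str]:
    out = []
    for x in X:
        if isinstance(x, ProteinSequence):
            out.append(x.residues)
        elif isinstance(x, str):
            out.append(x)
        else:
            raise TypeError(
                "X must be a sequence of residue strings or ProteinSequence objects"
            )
    if not out:
        raise ValueError("X is empty")
    return out


class DipeptideComposition(TransformerMixin, BaseEstimator):
    """Transform protein sequences into dipeptide-composition vectors.

    Stateless: the 400-dipeptide vocabulary is fixed, so ``fit`` only
    validates input. ``transform`` returns an (n, 400) array of overlapping
    dipeptide frequencies, each row summing to 1.
    """

    def fit(self, X, y=None):
        _residue_strings(X)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        return composition_matrix(_residue_strings(X))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(DIPEPTIDES, dtype=object)


class ScoreCardClassifier(ClassifierMixin, BaseEstimator):
    """Protein-solubility classifier by a dipeptide propensity score card.

    Fitting builds the initial statistical card from the two classes'
    dipeptide compositions and, with ``optimize=True``, refines it with the
    intelligent genetic algorithm maximizing ``w1 * AUC + w2 * R`` under
    stratified k-fold validation. The decision threshold maximizes training
    accuracy of the rule "score > threshold => soluble".

    Parameters follow the optimizer defaults (population 40, 20 generations,
    per-gene mutation probability 0.01, weights 0.9/0.1, 10 folds). ``y`` may
    be the string labels "soluble"/"insoluble" or 0/1 (1 = soluble).

    Attributes (after fit): ``card_`` (the trained :class:`ScoreCard`),
    ``scores_`` (its 400 dipeptide scores), ``threshold_``,
    ``initial_card_``, ``aa_scores_`` (derived residue scores), ``classes_``.
    """

    def __init__(
        self,
        optimize: bool = False,
        npop: int = 40,
        ps: float = 1.0,
        pm: float = 0.01,
        generations: int = 20,
        w1: float = 0.9,
        w2: float = 0.1,
        k_folds: int = 10,
        oa_factors: int = 15,
        n_runs: int = 1,
        random_state: int = 0,
    ) -> None:
        self.optimize = optimize
        self.npop = npop
        self.ps = ps
        self.pm = pm
        self.generations = generations
        self.w1 = w1
        self.w2 = w2
        self.k_folds = k_folds
        self.oa_factors = oa_factors
        self.n_runs = n_runs
        self.random_state = random_state

    def _labels_to_binary(self, y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "USO":
            valid = {SOLUBLE, INSOLUBLE}
            bad = set(np.unique(y)) - valid
            if bad:
                raise ValueError(f"unknown labels {sorted(bad)}; expected {sorted(valid)}")
            return np.array([1 if lab == SOLUBLE else 0 for lab in y], dtype=int)
        return y.astype(int)

    def fit(self, X, y):
        seqs = _residue_strings(X)
        yb = self._labels_to_binary(y)
        if len(seqs) != yb.size:
            raise ValueError("X and y differ in length")
        if set(np.unique(yb)) != {0, 1}:
            raise ValueError("y must contain both classes")
        y_arr = np.asarray(y)
        self.classes_ = np.unique(y_arr)

        entries = [
            (ProteinSequence(id=f"q{i}", residues=s), SOLUBLE if b else INSOLUBLE)
            for i, (s, b) in enumerate(zip(seqs, yb))
        ]
        train = LabeledDataset(entries)

        initial = build_initial_ssm(train)
        self.initial_card_ = initial
        if self.optimize:
            cfg = _iga.IGAConfig(
                npop=self.npop,
                ps=self.ps,
                pm=self.pm,
                generations=self.generations,
                w1=self.w1,
                w2=self.w2,
                k_folds=self.k_folds,
                seed=self.random_state,
                oa_factors=self.oa_factors,
            )
            if self.n_runs > 1:
                card, table = _iga.multi_run_select(train, cfg, self.n_runs, initial=initial)
                self.run_table_ = table
            else:
                card, log = _iga.optimize(initial, train, cfg)
                self.run_log_ = log
        else:
            card = ScoreCard(scores=initial.scores.copy(), provenance=dict(initial.provenance))

        X_comp = composition_matrix(seqs)
        train_scores = X_comp @ card.scores
        card.threshold, self.train_accuracy_ = select_threshold(train_scores, yb)
        self.card_ = card
        self.scores_ = card.scores
        self.threshold_ = float(card.threshold)
        self.aa_scores_ = amino_acid_scores(card.scores)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Solubility score minus threshold; positive means soluble."""
        check_is_fitted(self, "card_")
        return composition_matrix(_residue_strings(X)) @ self.scores_ - self.threshold_

    def solubility_scores(self, X) -> np.ndarray:
        """Raw weighted-sum solubility scores on the card's [0, 1000] scale."""
        check_is_fitted(self, "card_")
        return composition_matrix(_residue_strings(X)) @ self.scores_

    def _positive_negative_labels(self):
        if self.classes_.dtype.kind in "USO":
            return SOLUBLE, INSOLUBLE
        return 1, 0

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "card_")
        pos, neg = self._positive_negative_labels()
        d = self.decision_function(X)
        return np.where(d > 0, pos, neg)

    def predict_with_reject(self, X, region_size: float) -> np.ndarray:
        """Predict with abstention inside a band of full width ``region_size``.

        Abstained entries carry the label "abstain" (object dtype output).
        """
        check_is_fitted(self, "card_")
        if region_size < 0:
            raise ValueError("region_size must be nonnegative")
        pos, neg = self._positive_negative_labels()
        d = self.decision_function(X)
        out = np.where(d > 0, pos, neg).astype(object)
        out[np.abs(d) <= region_size / 2.0] = "abstain"
        return out
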