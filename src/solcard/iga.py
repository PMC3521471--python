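"""Score-card optimization by an intelligent genetic algorithm (IGA).

The 400 dipeptide scores are a single real-valued chromosome constrained to
[0, 1000]. Fitness rewards both discrimination and conservation:

    Fit = W1 * AUC + W2 * R

where AUC is the mean area under the ROC curve over the validation folds of a
stratified k-fold partition of the training set (scores from the candidate
card), and R is the Pearson correlation between the candidate's derived
amino-acid scores and those of the initial statistical card. The correlation
term anchors the optimized card to the statistical signal so the search does
not wander into uninterpretable score assignments.

The "intelligent" crossover is an orthogonal-array (OA) divide-and-conquer
recombination suited to long chromosomes: the genes are cut into contiguous
blocks, a two-level OA over blocks enumerates a small, balanced set of block
exchanges between the two parents, all OA rows are evaluated, and the best
row plus a main-effect-predicted combination become the children. Every child
gene is inherited verbatim from one parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .features import amino_acid_scores, composition_matrix
from .metrics import FitnessResult, confusion_metrics, pearson_r, roc_auc
from .scorecard import ScoreCard, select_threshold, solubility_score
from .seq_io import LabeledDataset

__all__ = [
    "IGAConfig",
    "Individual",
    "FitnessEvaluator",
    "fitness",
    "orthogonal_array",
    "intelligent_crossover",
    "mutate",
    "optimize",
    "multi_run_select",
]

GENE_LOW, GENE_HIGH = 0.0, 1000.0
N_GENES = 400


@dataclass
class IGAConfig:
    """Optimizer settings.

    Defaults are the standard operating point: population 40, selection
    fraction 1.0, mutation probability 0.01 per gene, 20 generations, fitness
    weights (0.9, 0.1), 10-fold cross-validation, 15 OA crossover blocks.
    """

    npop: int = 40
    ps: float = 1.0
    pm: float = 0.01
    generations: int = 20
    w1: float = 0.9
    w2: float = 0.1
    k_folds: int = 10
    seed: int = 0
    oa_factors: int = 15

    def __post_init__(self) -> None:
        if self.npop < 2:
            raise ValueError("npop must be >= 2")
        if not 0.0 <= self.pm <= 1.0:
            raise ValueError("pm must lie in [0, 1]")
        if self.w1 + self.w2 <= 0:
            raise ValueError("w1 + w2 must be positive")
        if self.oa_factors < 2:
            raise ValueError("need at least 2 crossover blocks")


@dataclass
class Individual:
    """A candidate score card (400 genes in [0, 1000]) with cached fitness."""

    genes: np.ndarray
    fitness: FitnessResult | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        if self.genes.shape != (N_GENES,):
            raise ValueError("chromosome must hold 400 genes")
        if self.genes.min() < GENE_LOW or self.genes.max() > GENE_HIGH:
            raise ValueError("genes out of [0, 1000]")

    @property
    def fit(self) -> float:
        if self.fitness is None:
            raise ValueError("individual not evaluated")
        return self.fitness.fitness


class FitnessEvaluator:
    """Evaluates candidate cards against one training set.

    Precomputes the composition matrix and the stratified fold membership,
    and caches results by gene content: OA crossover re-evaluates overlapping
    candidates heavily, and caching changes nothing semantically.
    """

    def __init__(self, train: LabeledDataset, cfg: IGAConfig,
                 initial_aa: np.ndarray) -> None:
        from sklearn.model_selection import StratifiedKFold

        train.require_both_classes()
        seqs, y = train.to_arrays()
        self.X = composition_matrix(seqs)
        self.y = y
        self.cfg = cfg
        self.initial_aa = np.asarray(initial_aa, dtype=float)
        k = min(cfg.k_folds, int(y.sum()), int((1 - y).sum()))
        if k < 2:
            raise ValueError("cannot build validation folds: a class is too small")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed % (2**31))
        self.val_folds = [val for _, val in skf.split(self.X, y)]
        self._cache: dict[bytes, FitnessResult] = {}
        self.n_evaluations = 0

    def __call__(self, genes: np.ndarray) -> FitnessResult:
        key = np.ascontiguousarray(genes).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.n_evaluations += 1
        scores = self.X @ genes
        auc = float(np.mean([roc_auc(scores[v], self.y[v]) for v in self.val_folds]))
        threshold, _ = select_threshold(scores, self.y)
        pred = (scores > threshold).astype(int)
        acc, sens, spec = confusion_metrics(pred, self.y)
        aa = amino_acid_scores(genes)
        if np.std(aa) == 0 or np.std(self.initial_aa) == 0:
            r = 0.0  # degenerate constant card: no conservation signal
        else:
            r = pearson_r(aa, self.initial_aa)
        result = FitnessResult(
            auc=auc,
            r=r,
            fitness=self.cfg.w1 * auc + self.cfg.w2 * r,
            train_accuracy=acc,
            test_accuracy=None,
            sensitivity=sens,
            specificity=spec,
            threshold=threshold,
        )
        self._cache[key] = result
        return result


def fitness(
    genes: np.ndarray,
    train: LabeledDataset,
    cfg: IGAConfig,
    initial_aa: np.ndarray,
) -> FitnessResult:
    """Evaluate one candidate card (convenience wrapper; see FitnessEvaluator)."""
    return FitnessEvaluator(train, cfg, initial_aa)(np.asarray(genes, dtype=float))


def orthogonal_array(n_factors: int) -> np.ndarray:
    """Two-level orthogonal array with ``n_factors`` columns.

    Standard construction: N = 2^ceil(log2(n_factors + 1)) rows; the level of
    factor j (1-based) in row i is popcount(i AND j) mod 2. Row 0 is all
    zeros. Any two columns contain each (level, level) pair equally often.
    """
    if n_factors < 1:
        raise ValueError("need at least one factor")
    n_rows = 1 << int(np.ceil(np.log2(n_factors + 1)))
    i = np.arange(n_rows)[:, None]
    j = np.arange(1, n_factors + 1)[None, :]
    return (np.bitwise_count(i & j) & 1).astype(np.int8)


def _gene_blocks(oa_factors: int) -> list[np.ndarray]:
    return np.array_split(np.arange(N_GENES), oa_factors)


def intelligent_crossover(
    p1: Individual,
    p2: Individual,
    evaluate: Callable[[np.ndarray], FitnessResult],
    oa_factors: int = 15,
) -> tuple[Individual, Individual]:
    """Orthogonal-array crossover of two evaluated parents.

    Returns (best OA row, main-effect child). Each OA row assembles a
    candidate by inheriting block b from parent 1 (level 0) or parent 2
    (level 1); all rows are evaluated. The main-effect child picks, per
    block, the level whose OA rows averaged the better fitness.
    """
    if p1.fitness is None or p2.fitness is None:
        raise ValueError("both parents must be evaluated before crossover")
    oa = orthogonal_array(oa_factors)
    blocks = _gene_blocks(oa_factors)

    def assemble(levels: Sequence[int]) -> np.ndarray:
        genes = p1.genes.copy()
        for b, lev in enumerate(levels):
            if lev:
                genes[blocks[b]] = p2.genes[blocks[b]]
        return genes

    rows = [assemble(oa[r]) for r in range(oa.shape[0])]
    results = [evaluate(g) for g in rows]
    fits = np.array([res.fitness for res in results])

    best_row = int(np.argmax(fits))
    c1 = Individual(genes=rows[best_row], fitness=results[best_row])

    main_levels = [
        int(fits[oa[:, b] == 1].mean() > fits[oa[:, b] == 0].mean())
        for b in range(oa_factors)
    ]
    c2_genes = assemble(main_levels)
    c2 = Individual(genes=c2_genes, fitness=evaluate(c2_genes))
    return c1, c2


def mutate(ind: Individual, pm: float, rng: np.random.Generator) -> Individual:
    """Per-gene uniform mutation: each gene is redrawn from [0, 1000] w.p. pm.

    Returns a new individual; fitness is invalidated iff any gene changed.
    """
    if not 0.0 <= pm <= 1.0:
        raise ValueError("pm must lie in [0, 1]")
    mask = rng.random(N_GENES) < pm
    if not mask.any():
        return Individual(genes=ind.genes.copy(), fitness=ind.fitness)
    genes = ind.genes.copy()
    genes[mask] = rng.uniform(GENE_LOW, GENE_HIGH, size=int(mask.sum()))
    return Individual(genes=genes, fitness=None)


def _rank_select(fits: np.ndarray, n_pool: int, rng: np.random.Generator) -> np.ndarray:
    """Linear-rank sampling without replacement; best rank gets largest weight."""
    order = np.argsort(-fits)  # best first
    weights = np.empty_like(fits)
    weights[order] = np.arange(len(fits), 0, -1, dtype=float)
    return rng.choice(len(fits), size=n_pool, replace=False, p=weights / weights.sum())


@dataclass
class RunLog:
    """Per-generation trace of one optimization run."""

    best_fitness: list[float] = field(default_factory=list)
    n_evaluations: int = 0
    final: FitnessResult | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"generation": np.arange(len(self.best_fitness)), "best_fitness": self.best_fitness}
        )


def optimize(
    initial: ScoreCard, train: LabeledDataset, cfg: IGAConfig
) -> tuple[ScoreCard, RunLog]:
    """Optimize a score card by the IGA; deterministic under ``cfg.seed``.

    The population is seeded with the initial card plus npop-1 uniform-random
    chromosomes. Each generation, a rank-selected mating pool is crossed
    member-by-member with the incumbent best; of the two parents and two
    children the best keeps the incumbent slot and the runner-up the member's
    slot, so the best fitness never decreases. Mutation spares the incumbent
    best. The returned card carries the accuracy-maximizing threshold on the
    pooled training scores.
    """
    rng = np.random.default_rng(cfg.seed)
    evaluate = FitnessEvaluator(train, cfg, amino_acid_scores(initial.scores))

    pop = [Individual(genes=initial.scores.copy())]
    for _ in range(cfg.npop - 1):
        pop.append(Individual(genes=rng.uniform(GENE_LOW, GENE_HIGH, N_GENES)))
    for ind in pop:
        ind.fitness = evaluate(ind.genes)

    log = RunLog()
    best_idx = int(np.argmax([ind.fit for ind in pop]))
    log.best_fitness.append(pop[best_idx].fit)

    for _ in range(cfg.generations):
        fits = np.array([ind.fit for ind in pop])
        n_pool = max(1, int(round(cfg.ps * cfg.npop)))
        pool = _rank_select(fits, n_pool, rng)
        for i in pool:
            if i == best_idx:
                continue
            c1, c2 = intelligent_crossover(pop[i], pop[best_idx], evaluate, cfg.oa_factors)
            four = sorted([pop[i], pop[best_idx], c1, c2], key=lambda ind: -ind.fit)
            pop[best_idx], pop[i] = four[0], four[1]
        for i in range(cfg.npop):
            if i == best_idx:
                continue  # the incumbent best is never mutated
            mutated = mutate(pop[i], cfg.pm, rng)
            if mutated.fitness is None:
                mutated.fitness = evaluate(mutated.genes)
            pop[i] = mutated
        best_idx = int(np.argmax([ind.fit for ind in pop]))
        log.best_fitness.append(pop[best_idx].fit)

    best = pop[best_idx]
    log.final = best.fitness
    log.n_evaluations = evaluate.n_evaluations
    card = ScoreCard(
        scores=best.genes.copy(),
        threshold=best.fitness.threshold,
        provenance={
            "kind": "optimized",
            "seed": cfg.seed,
            "w1": cfg.w1,
            "w2": cfg.w2,
            "npop": cfg.npop,
            "generations": cfg.generations,
        },
    )
    return card, log


def multi_run_select(
    train: LabeledDataset,
    cfg: IGAConfig,
    n_runs: int,
    initial: ScoreCard | None = None,
    test: LabeledDataset | None = None,
) -> tuple[ScoreCard, pd.DataFrame]:
    """Run the optimizer ``n_runs`` times and keep the most accurate card.

    Run i uses seed ``cfg.seed + i``. The card with the highest training
    accuracy wins. The returned table has one row per run (fitness, training
    and test accuracy, sensitivity, specificity, AUC, R, threshold) plus mean
    and standard-deviation rows.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if initial is None:
        from .scorecard import build_initial_ssm

        initial = build_initial_ssm(train)
    rows = []
    cards = []
    for i in range(n_runs):
        card, log = optimize(initial, train, replace(cfg, seed=cfg.seed + i))
        res = log.final
        row = res.as_row()
        row["run"] = i + 1
        if test is not None:
            preds = [1 if solubility_score(s, card) > card.threshold else 0
                     for s in test.sequences]
            _, y_test = test.to_arrays()
            row["test_accuracy"] = confusion_metrics(np.array(preds), y_test)[0]
        rows.append(row)
        cards.append(card)
    table = pd.DataFrame(rows).set_index("run").astype(float)
    table.loc["mean"] = table.mean()
    table.loc["std"] = table.iloc[:-1].std(ddof=1) if n_runs > 1 else 0.0
    best = int(np.argmax([r["train_accuracy"] for r in rows]))
    return cards[best], table
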