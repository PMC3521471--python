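# Methods

## Model

The scoring-card method is a linear model over dipeptide composition with a
thresholded decision rule. Sequences are strings over the 20 standard
residues; a length-`L` sequence contributes its `L − 1` overlapping
dipeptide windows (the field-standard counting; class totals then equal the
summed sequence lengths minus the number of sequences). The 400 dipeptides
are indexed first-residue-major, alphabetically in both positions, and that
order is frozen so card files are interchangeable between installations.

**Initial card.** Per dipeptide, raw propensity = soluble-class composition
minus insoluble-class composition (compositions are pooled class counts over
class totals). Scores are the linear min–max map of the raw values onto
`[0, 1000]`; a freshly built card therefore spans 0 and 1000 exactly (the
endpoints are pinned against floating-point round-off). The map is invariant
to adding a constant to all raw values, and swapping the class labels maps
every score `s` to `1000 − s`. If all raw values coincide the card would be
arbitrary, so construction raises (`DegenerateDataError`) instead of
returning a constant card. Scores stay floating-point internally; only
reports round to integers.

**Decision rule.** Soluble iff `S(P) > t`, strictly; a score exactly at the
threshold is insoluble. Threshold candidates are the midpoints between
consecutive distinct training scores plus one sentinel below the minimum and
one above the maximum (midpoints make the cut margin-symmetric); among
equally accurate candidates the smallest wins, making selection
deterministic. With an uncertainty band of full width `u`, scores within
`u/2` of the threshold (inclusive) yield abstention.

**Residue scores.** The score of residue A is the mean of the 40 values
`{S(AX)} ∪ {S(XA)}`; `S(AA)` belongs to both sets and deliberately counts
twice. A 39-term mean over unique dipeptides would be equally defensible;
the 40-term form is the simpler convention and is fixed here as a documented
constant of the package.

## Genetic refinement

The optimizer treats the 400 scores as one chromosome in `[0, 1000]^400`
and maximizes `W1·AUC + W2·R`:

- **AUC**: the training set is split by stratified k-fold (default k = 10,
  shuffled, seeded); the candidate card scores each validation fold and the
  per-fold AUCs (rank/Mann–Whitney form, exact under ties) are averaged.
  Averaging per-fold AUCs rather than pooling scores is a choice; with a
  common card the two differ only through fold composition.
- **R**: Pearson correlation between the candidate's derived residue scores
  and those of the initial card — a conservation prior that keeps the
  optimized card close to the statistical signal.

Defaults: population 40 (the initial card plus 39 uniform-random
chromosomes), selection fraction 1.0, per-gene mutation probability 0.01,
20 generations, weights (0.9, 0.1), 15 crossover blocks. Tests and the
acceptance study run a scaled-down setting (population 10, 5 generations)
chosen as the package's desk-scale default for the synthetic study; the
algorithm is identical.

**Crossover.** The chromosome is cut into `oa_factors` contiguous blocks
(default 15; `numpy.array_split`, so block sizes differ by at most one). A
two-level orthogonal array with `N = 2^ceil(log2(oa_factors + 1))` rows —
the classical construction `level(i, j) = popcount(i AND j) mod 2` —
enumerates balanced block exchanges between the two parents. All rows are
evaluated; the best row is child 1, and child 2 takes, per block, the level
whose rows averaged the better fitness (the main-effect prediction). Every
child gene equals one parent's gene at that locus.

**Population update.** Each selected individual is crossed with the
incumbent best. Among the two parents and two children, the best occupies
the incumbent slot and the runner-up the member's slot. This keeps the
population size constant, guarantees the best individual survives, and
makes the per-generation best fitness non-decreasing; it is one concrete
resolution of the "keep the best two of four" elitist update, chosen for
those invariants. Mutation redraws each gene uniformly from `[0, 1000]`
with probability `pm`, never touching the incumbent best. Selection is
linear-rank sampling without replacement so fractions below 1.0 also work.
Fitness evaluations are cached on gene content — OA crossover revisits
identical candidates — with no semantic effect. One master seed drives
population init, fold assignment, selection and mutation; identical
configurations reproduce identical cards.

Multi-run selection repeats the optimization with consecutive seeds and
keeps the card with the highest training accuracy, logging one row per run
plus mean and standard deviation. Reported training accuracy is the refit
accuracy on the full training set at the card's threshold (not the CV
estimate); the run log carries both it and the CV AUC, and the two are not
forced to agree.

## Synthetic planted-propensity data

The generator draws each sequence from a first-order Markov chain over
residues: class-specific transition weights are
`base_freq(next) · exp(±effect_size · propensity(current, next))`, with `+`
for the soluble class and `−` for the insoluble class, rows normalized.
First-order dependence (rather than i.i.d. residues) is what makes a
dipeptide-level signal genuinely plantable. Defaults — the generator's
standard study conditions — are: lengths uniform on 100–300 (typical
bacterial-protein lengths), planted propensities i.i.d. standard normal,
effect size 1.0, uniform base residue frequencies, 200 + 200 training
sequences. At effect size 0 the two classes are exchangeable by
construction.

What the generator does *not* emulate: realistic amino-acid usage,
domain/secondary-structure organization, length–solubility correlation,
fusion tags, or any experimental-condition covariate (pH, temperature,
additives). Passing the synthetic tests therefore shows the estimator
recovers a planted dipeptide signal and is calibrated under the null; it
does not certify accuracy on real expression data, where reported
accuracies for this model family are in the mid-80s (%) on curated corpora
and the signal is far weaker than an effect-size-1.0 plant. Indeed at these
standard conditions the planted signal is strong enough that the initial
card alone reaches training accuracy 1.0 and the genetic stage can only
confirm, not improve, it; the optimizer's behaviour is exercised through
its invariants (elitism, inheritance, reproducibility) rather than through
an accuracy gain.

**Recovery diagnostic.** Spearman rank correlation between the planted
propensity vector and the learned card, restricted to dipeptides observed
at least 5 times in the training data (the learned score of a never-seen
dipeptide is an artifact of min–max normalization, not signal).

**Null calibration.** With no effect, the expected held-out AUC of any
learned card is 0.5, but a single replicate carries both test-sampling and
card-noise variance (empirically ≈ 0.045 at 400 training and 400 held-out
sequences), so calibration is assessed on the mean over 5 independent
replicates of the full train-plus-heldout experiment.

## Data handling

FASTA parsing is case-insensitive via Biopython; records with non-standard
residues (B, J, O, U, X, Z, `*`) or fewer than two residues are dropped with
a logged warning by default, or rejected in strict mode. Stratified
train/test splitting rounds per-class train counts half-up (0.8 of class
sizes 285/672 gives 228/538); published corpora were often split without
stratification, and such splits are not reconstructible here. Stratified
k-fold partitioning guarantees each sequence appears in exactly one
validation fold with per-fold class proportions within one sequence of the
global ones.

Property tables are flat tab-delimited files (id, description, 20 values in
alphabetical residue order, `NA` allowed); the AAindex database itself is
not bundled. Properties containing any `NA` are skipped by correlation
analyses, never imputed; keyword grouping is a case-insensitive substring
match on the description, and group variance is the population variance
(so a single-property group reports variance 0). Three published 20-value
reference scales ship with the package (`solcard.reference`): a residue
solubility score set from a scoring-card study of *E. coli* overexpression
solubility, the α-helical propensity scale P_α, and AAindex KUMS000103.

Score-card files are two-column TSV with `#` header lines for threshold and
provenance, written at repr precision so a save/load round-trip is
bit-exact. Histogram bins are half-open `[lo, hi)` with the last bin
closed. Score histograms, the accuracy-versus-abstention curve, positional
score profiles and the 20×20 heat-map table are exported as plain tables;
no plotting is performed.

## Known limitations

- A card is specific to the experimental conditions of its training corpus;
  cards trained under one condition transfer poorly to another, and this
  package makes no attempt to correct for that.
- The linear weighted-sum score ignores positional and higher-order
  interactions (tripeptides and beyond).
- Threshold selection optimizes overall accuracy only; cost-sensitive or
  prevalence-corrected thresholds are out of scope.
- The optimizer is a stochastic search; different seeds give different
  cards of similar fitness, which is why multi-run selection exists.
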