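# Methods

## The model

A pattern is a triple {P, S, r}: attributes P = {P₁, …, P_w}, values
S = {v₁, …, v_w}, and a matching-ratio threshold r ∈ (0, 1]. A record
matches when at least r·w of its pattern cells equal the corresponding
values. The threshold is stored as a float but tested in exact integer
form, `matched_count ≥ ⌈r·w − ε⌉` (ε = 1e-9), which agrees with the
floating comparison for every rational grid point k/w up to w = 64
(verified exhaustively in the tests). The comparison is ≥, so a record
matching exactly r·w values matches. The denominator is the pattern width
w, not the table width m: a threshold meaning "2 of the 3 named
attributes" must not change when unrelated columns are added or removed.

Missing cells compare unequal to everything — including another missing
cell and including a hypothetical missing pattern value. A record with all
pattern cells missing therefore never matches at any r. This is the
mechanism by which the model tolerates noise: a missing or corrupted cell
costs one potential match rather than invalidating the record, and no
imputation is ever performed.

## Training

1. **Chi-squared attribute selection.** Pearson statistic without Yates
   continuity correction on each attribute × (T = t vs T ≠ t) table built
   from non-missing cells, df = (rows−1)(cols−1). Attributes are ranked by
   ascending p-value, ties by descending statistic and then original column
   order, then truncated to the top `width` or filtered at `p_cutoff`
   (default 0.05; exactly one of the two modes is active). An attribute
   with a single observed category gets statistic 0 / p 1 and ranks last
   rather than erroring. No minimum expected count is enforced — the
   intended datasets are small — but a warning is logged when an expected
   cell falls below 5. Attributes still carrying raw numerics are rejected;
   categorization must be explicit.
2. **Value heuristic.** For each selected attribute the 2 × categories
   count table (rows T = t / T ≠ t, non-missing cells) is converted to
   row-wise percentages and compared column-wise. The default
   `dominant-positive` mode returns, among categories where the positive
   percentage is at least the negative one, the category with the maximal
   positive percentage, falling back to the global positive-row argmax when
   no category qualifies; `max-difference` returns the argmax of
   (positive% − negative%). The phrasing of the column-wise comparison
   admits both readings, so both are implemented with one documented
   default; ties break by category domain order.
3. **Threshold search.** r is swept over exactly {1/w, …, w/w}; each grid
   point is evaluated on the training data and the best G-mean wins. The
   G-mean optimization uses training data only. Ties resolve to the largest
   r by default — the strictest pattern, favoring specificity on unseen
   data — configurable to smallest.
4. **Log-likelihood fallback.** Iff the training positive/negative ratio is
   strictly below `imbalance_trigger_ratio` (default 2, the smallest
   integer above the balanced case), class-conditional probabilities of
   every selected attribute are estimated with additive smoothing
   (pseudo-count 1 by default): P(v | class) = (count + s)/(n_class +
   s·|domain|) over non-missing cells, so every in-domain category has
   positive mass and log scores are total. A value outside the training
   domain scores s/(n_class + s·|domain|), treated as a hypothetical extra
   category without renormalization. Class priors come from training
   frequencies and are included in the score by default (the comparison is
   then an unnormalized posterior, i.e. naive-Bayes scoring); a flag zeroes
   them for a pure-likelihood comparison.

Prediction: positive iff the pattern matches OR (the fallback exists and
the positive log score strictly exceeds the negative one; ties are
negative). With no fallback, prediction is exactly pattern matching.

## Evaluation framework

Repeated stratified k-fold cross-validation (defaults k = 10, 20 runs).
Folds are built by shuffling each class with the run seed and dealing
round-robin, guaranteeing per-fold positive counts within one of each
other; k may equal n (leave-one-out degenerate case). All comparators in a
run share the folds. Up-sampling, when requested, duplicates training-fold
positives uniformly with replacement until #pos/#neg first reaches the
requested ratio — negatives untouched, no synthetic records, test folds
never resampled — so test metrics always reflect the original prevalence.
Down-sampling is rejected by design. A run-level value is the mean over the
k test folds; the report stores all run-level values and summarizes
mean ± sd over runs. A comparator failure on a fold is recorded in the
report (the run value becomes NaN), never silently skipped.

The one-sided paired Wilcoxon signed-rank test ("reference > competitor")
drops zero differences, uses average ranks with the standard tie variance
correction Σ(t³−t)/48, and by default applies the normal approximation
**without** continuity correction — with 20 strictly positive distinct
differences this gives z = 105/√717.5 ≈ 3.920 and p ≈ 4.43 × 10⁻⁵ (with the
correction it would be ≈ 4.8 × 10⁻⁵). Flags enable the continuity
correction or the exact distribution; tests cross-check all three variants
against an independent implementation.

The random baseline predicts positive with probability ½ from a seeded
generator; its theoretical sensitivity is 0.5 and precision equals the
prevalence, giving F1 = 2·p·0.5/(p + 0.5) (≈ 0.23 at p = 0.149) — useful as
the non-informative floor any real method must clear. Conventional
interpretable comparators (logistic regression, naive Bayes, decision tree)
plug in as scikit-learn estimators behind a one-hot adapter in which a
missing cell encodes as all-zeros; their third-party numerics are
illustrative, not a contract.

## Synthetic generator

Emulates the target regime: minority prevalence in (0, 0.5) with an exact
positive count round(n·prevalence) (exact rather than Bernoulli so fold
stratification and the imbalance trigger are deterministic test surfaces);
a planted pattern whose attributes carry the planted value with probability
`adherence_pos` in positives and `adherence_neg` in negatives, else a
uniform other category; uniform target-independent noise attributes; and
per-cell missingness (never on the target). Defaults — n = 500, prevalence
0.10, width 4, adherence 0.9/0.2, 8 noise attributes, 3 categories, 1%
missing — describe a recoverable configuration typical of the intended
data. What the generator does **not** emulate: correlated predictors,
class-dependent missingness, multi-category targets, or the covariance
structure of derived gene-expression components; passing recovery tests
therefore demonstrates correctness of the algorithm under independence, not
performance on any particular clinical dataset.

## Data handling

CSV (first row = names) and ARFF are supported; "?", "N/A" and the empty
string are missing tokens by default (configurable). ARFF category domains
come from the header and may exceed observed values; CSV domains are the
observed values in first-appearance order; the effective domain is the
union, declared order first. Columns whose non-missing cells all parse as
numbers are held as raw floats until categorization. Categorization rules
— half-open [low, high) interval bins, a sign rule assigning 0 to the ≤ 0
label, and a two-source combination rule — propagate missing inputs and
raise on values outside every bin, forcing rule completeness. Writing then
reading a dataset round-trips it exactly in both formats.

## Problem sizes and numerical choices

The test suite and acceptance script run on synthetic data at n ≤ 500 with
up to 12 attributes — ample for the statistics involved (the chi-squared
statistics of planted attributes at adherence 0.9/0.2 are two orders of
magnitude above the noise floor) while keeping the full suite under a
minute. Recovery experiments use top-K width selection with K equal to the
planted width: under p-cutoff selection roughly 5% of noise attributes pass
0.05 per seed by chance, so exact-set recovery is a property of the top-K
mode. Threshold comparisons use an ε of 1e-9 against float division;
p-value ties in attribute ranking are broken deterministically; all
randomness flows from explicit integer seeds (numpy Generator), and
derived seeds stay below 2³¹.

## Limitations

Single pattern, single value per attribute (no disjunctions); no automatic
binning of numeric attributes; greedy per-attribute value choice need not
be jointly optimal; the chi-squared ranking ignores attribute interactions;
up-sampling by duplication can overfit duplicated positives at high ratios.
These mirror the intended use — a first, interpretable screen of an
existing repository before a formal study — rather than a maximally
predictive model.
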