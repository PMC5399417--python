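# patdisc

Interpretable pattern discovery for predicting **rare categorical outcomes**
in clinical-repository-style data — tables of nominal attributes with
scattered missing cells, where the event of interest (a death, a bleed)
occurs in only 5–15% of records and ordinary classifiers collapse onto the
majority class.

The model is a single human-readable rule, a *pattern* {P, S, r}: a subset
of attributes P = {P₁, …, P_w}, one value per attribute S = {v₁, …, v_w},
and a matching-ratio threshold r ∈ (0, 1]. A record D matches when

    count(D[P₁] = v₁, …, D[P_w] = v_w) / w  ≥  r,

so at least ⌈r·w⌉ of the w attribute-values must agree; missing cells count
as mismatches, which is how the rule tolerates noisy data without
imputation. Training is a three-stage heuristic:

1. **Attributes** — chi-squared test of independence between each attribute
   and the binarized target (T = t vs T ≠ t); keep the top-K or all with
   p ≤ 0.05.
2. **Values** — for each selected attribute, compare the class-conditional
   category percentages column-wise and pick the category most associated
   with T = t.
3. **Threshold** — sweep r over the exact grid {1/w, …, w/w} and keep the
   grid point maximizing the **training G-mean** = √(sensitivity × specificity),
   a criterion that, unlike accuracy, cannot be gamed by predicting the
   majority everywhere.

When the training positive/negative ratio is below 2, a Laplace-smoothed
naive-Bayes log-likelihood table over the selected attributes is fitted as
a fallback: a test record is positive if the pattern matches **or** its
positive-class log score strictly exceeds the negative one.

An evaluation framework reproduces the accompanying protocol: repeated
(default 20×) stratified 10-fold cross-validation in which all compared
methods share the same folds, optional up-sampling by duplication of
training-fold positives only (test folds always keep the original
prevalence), a fair-coin random baseline (theoretical sensitivity 0.5,
precision = prevalence, hence F1 = 2·p·0.5/(p + 0.5)), and one-sided paired
Wilcoxon signed-rank comparisons (normal approximation without continuity
correction). A seeded synthetic generator plants a known pattern in
imbalanced data so everything is testable end to end.

## Worked example

`python examples/train_pattern.py` trains on a six-record illustrative
table of post-PCI patients (target Bleeding = Yes, prevalence 2/6):

```
discovered rule : PCI History = Yes, CRP = Abnormal, Hemoglobin = Abnormal ; r = 2/3 (67%)
chi-squared p   : {'PCI History': 0.083, 'CRP': 0.083, 'Hemoglobin': 0.248}
fallback fitted : True (pos/neg ratio 0.5 < 2)
training metrics: sensitivity 1.00, specificity 0.75, F1 0.80, G-mean 0.866
```

A patient matching at least 2 of the 3 attribute-values is predicted to
bleed: both true bleeders match (sensitivity 1.0) at the cost of one false
alarm (specificity 0.75); the r-grid search picked 2/3 because its G-mean
√(1.0 × 0.75) ≈ 0.866 beats both r = 1/3 and r = 1 (each ≈ 0.707).

`python examples/cross_validate.py` runs the shared-fold CV protocol on a
synthetic cohort (n = 500, prevalence 10%, planted 4-attribute pattern)
against logistic regression and the fair-coin baseline, and prints the
per-method mean ± sd with Wilcoxon p-values.
`python examples/simulate_and_categorize.py` shows the generator, the
CSV/ARFF round-trip, and numeric-to-category rules (sign rule, half-open
interval bins).

## Command line

For shell use the same pipeline is exposed as a thin CLI:

```bash
patdisc simulate --config sim.yaml   # synthetic dataset + ground-truth pattern
patdisc train    --config run.yaml   # final model on full data + rule line
patdisc cv       --config run.yaml   # repeated CV report (JSON + CSV)
```

Configs are YAML/JSON naming the input table (CSV or ARFF), the target
attribute and positive value, optional categorization rules, and the
discovery/CV settings; see `tests/test_cli.py` for minimal examples.

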