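"""Repeated stratified cross-validation against baselines on synthetic data.

Generates an imbalanced dataset with a planted 4-attribute pattern (10%
prevalence, 1% missing cells), then runs 5 runs of 5-fold CV in which
pattern discovery, logistic regression and a fair-coin baseline share the
same folds.  The Wilcoxon p-values ask whether pattern discovery's run-level
scores rank above each competitor's.
"""

from sklearn.linear_model import LogisticRegression

from patdisc import (
    CVPlan,
    DiscoveryConfig,
    PatternDiscovery,
    RandomBaseline,
    SklearnComparator,
    SyntheticSpec,
    generate,
    prevalence,
    random_baseline_theoretical,
    run_experiment,
)

spec = SyntheticSpec(seed=42)  # n=500, prevalence 0.10, planted width 4
dataset, truth = generate(spec)
prev = prevalence(dataset, spec.target)
print(f"dataset: n={dataset.n}, prevalence {prev.prevalence:.1%}, "
      f"planted rule {truth.to_line()}")

plan = CVPlan(k=5, runs=5, seed=0)
report = run_experiment(
    dataset,
    spec.target,
    [
        PatternDiscovery(DiscoveryConfig(width=4, p_cutoff=None)),
        SklearnComparator(LogisticRegression(max_iter=1000), "logistic_regression"),
        RandomBaseline(),
    ],
    plan,
)

for row in report.summary_rows():
    print(
        f"{row['method']:>20s}: F1 {row['f1_mean']:.3f}±{row['f1_sd']:.3f}  "
        f"G-mean {row['g_mean_mean']:.3f}±{row['g_mean_sd']:.3f}"
    )
theory = random_baseline_theoretical(prev.prevalence)
print(f"fair-coin theory    : F1 {theory['f1']:.3f}        G-mean {theory['g_mean']:.3f}")
for name in ("logistic_regression", "random_baseline"):
    p = report.wilcoxon[(name, "original", "g_mean")]
    print(f"Wilcoxon (G-mean) pattern discovery > {name}: p = {p:.3g}")
print(
    "A small p-value means pattern discovery's per-run G-means consistently "
    "rank above\nthat method's across the shared folds."
)
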