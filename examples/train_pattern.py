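"""Train a pattern on a small categorical table and read the rule it finds.

Builds the six-record illustrative dataset (post-PCI bleeding, prevalence
2/6) in memory, trains the pattern-discovery classifier with the top three
chi-squared attributes, and prints the discovered rule and its training
metrics.  The rule reads: a patient matching at least 2 of the 3
attribute-values is predicted to bleed.
"""

import pandas as pd

from patdisc import (
    Dataset,
    DiscoveryConfig,
    MISSING,
    TargetSpec,
    evaluate,
    metrics_from_counts,
    train,
)

df = pd.DataFrame(
    {
        "Gender": ["Male", "Female", "Male", MISSING, "Female", "Male"],
        "PCI History": ["Yes", "No", "No", "Yes", "Yes", "No"],
        "Hemoglobin": ["Abnormal", "Abnormal", MISSING, "Normal", MISSING, "Normal"],
        "Diabetes": ["No", MISSING, "No", "No", "No", "No"],
        "CRP": ["Abnormal", "Abnormal", "Normal", "Normal", "Abnormal", "Normal"],
        "Bleeding": ["Yes", "No", "No", "No", "Yes", "No"],
    },
    dtype=object,
)
dataset = Dataset(df, target_name="Bleeding")
target = TargetSpec("Bleeding", "Yes")

clf = train(dataset, target, DiscoveryConfig(width=3, p_cutoff=None))
m = metrics_from_counts(evaluate(clf.pattern, dataset, target))

print("discovered rule :", clf.pattern.to_line())
print("chi-squared p   :", {a: round(p, 3) for a, p in clf.p_values.items()})
print("fallback fitted :", clf.likelihoods is not None, "(pos/neg ratio 0.5 < 2)")
print(
    f"training metrics: sensitivity {m.sensitivity:.2f}, specificity "
    f"{m.specificity:.2f}, F1 {m.f1:.2f}, G-mean {m.g_mean:.3f}"
)
print(
    "Sensitivity 1.0 with specificity 0.75 means the 2-of-3 match catches "
    "both bleeders\nwhile flagging one non-bleeder; G-mean 0.866 is what the "
    "r-grid search maximized."
)
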