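"""Seeded generator of imbalanced categorical datasets with a planted pattern.

Emulates the data regime of routine clinical repository extracts: a rare
nominal target (prevalence well below 50%), a handful of attribute-values
genuinely enriched in positives, many target-independent noise attributes,
and sparse per-cell missingness.  The planted pattern is returned as ground
truth so recovery can be measured.

The positive count is exact — ``round(n * prevalence)`` records — rather
than Bernoulli-sampled, so stratified folds and the imbalance-trigger logic
are deterministic given a seed.  Non-planted cells fall back to a uniform
draw over the remaining categories, the simplest null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MISSING, Dataset, TargetSpec
from .pattern import Pattern

__all__ = ["SyntheticSpec", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator conditions.

    Defaults describe a typical recoverable configuration: 500 records at
    10% prevalence, a planted 4-attribute pattern carried per-attribute with
    probability 0.9 by positives and 0.2 by negatives, 8 noise attributes,
    3 categories per attribute, and 1% per-cell missingness.
    """

    n: int = 500
    prevalence: float = 0.10
    planted_width: int = 4
    adherence_pos: float = 0.9
    adherence_neg: float = 0.2
    n_noise_attrs: int = 8
    categories_per_attr: int = 3
    missing_rate: float = 0.01
    seed: int = 0
    target_name: str = "Outcome"
    positive_value: str = "Yes"
    negative_value: str = "No"

    def __post_init__(self):
        if not 0 < self.prevalence < 0.5:
            raise ValueError("prevalence must be in (0, 0.5): the imbalance regime")
        if self.planted_width < 1:
            raise ValueError("planted_width must be >= 1")
        if self.categories_per_attr < 2:
            raise ValueError("need >= 2 categories per attribute")
        for p in (self.adherence_pos, self.adherence_neg, self.missing_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    @property
    def target(self) -> TargetSpec:
        return TargetSpec(self.target_name, self.positive_value)


def generate(spec: SyntheticSpec) -> tuple[Dataset, Pattern]:
    """Draw a dataset and return it with the planted ground-truth pattern.

    Exactly ``round(n * prevalence)`` positives; planted attributes carry
    the planted value with probability ``adherence_pos`` (positives) or
    ``adherence_neg`` (negatives), else a uniformly random other category;
    noise attributes are uniform and independent of the target; MISSING is
    injected per predictor cell at ``missing_rate`` (never on the target).
    Byte-identical output for a given seed.
    """
    total_attrs = spec.planted_width + spec.n_noise_attrs
    if spec.planted_width > total_attrs:
        raise ValueError("planted_width exceeds total attribute count")
    rng = np.random.default_rng(spec.seed)
    n_pos = round(spec.n * spec.prevalence)
    labels = np.array([True] * n_pos + [False] * (spec.n - n_pos))
    rng.shuffle(labels)

    cats = [f"c{j}" for j in range(spec.categories_per_attr)]
    planted_attrs = tuple(f"signal_{i}" for i in range(spec.planted_width))
    noise_attrs = tuple(f"noise_{i}" for i in range(spec.n_noise_attrs))
    planted_values = tuple(
        cats[int(rng.integers(spec.categories_per_attr))]
        for _ in range(spec.planted_width)
    )

    cols: dict[str, pd.Series] = {}
    for attr, planted in zip(planted_attrs, planted_values):
        adherence = np.where(labels, spec.adherence_pos, spec.adherence_neg)
        carries = rng.random(spec.n) < adherence
        others = [c for c in cats if c != planted]
        fallback = rng.integers(len(others), size=spec.n)
        col = np.where(carries, planted, np.array(others, dtype=object)[fallback])
        cols[attr] = pd.Series(list(col), dtype=object)
    for attr in noise_attrs:
        draws = rng.integers(spec.categories_per_attr, size=spec.n)
        cols[attr] = pd.Series([cats[j] for j in draws], dtype=object)

    if spec.missing_rate > 0:
        for attr in planted_attrs + noise_attrs:
            mask = rng.random(spec.n) < spec.missing_rate
            s = cols[attr]
            cols[attr] = pd.Series(
                [MISSING if m else v for v, m in zip(s, mask)], dtype=object
            )

    cols[spec.target_name] = pd.Series(
        [spec.positive_value if y else spec.negative_value for y in labels],
        dtype=object,
    )
    domains = {a: tuple(cats) for a in planted_attrs + noise_attrs}
    domains[spec.target_name] = (spec.positive_value, spec.negative_value)
    dataset = Dataset(
        pd.DataFrame(cols), target_name=spec.target_name, domains=domains
    )
    truth = Pattern(attrs=planted_attrs, values=planted_values, r=1.0)
    return dataset, truth
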