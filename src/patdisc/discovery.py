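"""Training and prediction for the pattern-discovery classifier.

Training is a three-stage heuristic — exhaustive search over attribute-value
combinations is intractable, so each stage is solved greedily:

1. **Attribute selection.**  A Pearson chi-squared test of independence is
   run between every categorical attribute and the binarized target
   (T = t vs T != t), over non-missing cells; attributes are ranked by
   ascending p-value and either the top W are kept or all with
   p <= p_cutoff.
2. **Value selection.**  For each selected attribute the two class-
   conditional percentage rows are compared column-wise and the category
   most associated with the positive class is chosen (see
   :func:`select_value` for the two comparison modes).
3. **Threshold search.**  The matching-ratio threshold r is swept over the
   exact grid {1/w, ..., w/w} and the grid point with the best *training*
   G-mean is kept.

When the training class ratio #pos/#neg is below ``imbalance_trigger_ratio``
(default 2, the smallest integer above the balanced case), a smoothed
naive-Bayes log-likelihood table over the selected attributes is also
fitted; at prediction time a record is positive when the pattern matches
OR the positive-class log score strictly exceeds the negative one, so weak
or ambiguous patterns do not silently miss every case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from .data_model import MISSING, Dataset, Record, TargetSpec, prevalence
from .pattern import Pattern, match, matched_counts

__all__ = [
    "DiscoveryConfig",
    "LikelihoodTable",
    "TrainedClassifier",
    "chi_squared_select",
    "select_value",
    "optimize_threshold",
    "fit_likelihoods",
    "train",
    "predict",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiscoveryConfig:
    """Knobs of the training pipeline.

    Exactly one of ``width`` (top-K attributes) or ``p_cutoff`` drives how
    many attributes the chi-squared stage keeps.  ``imbalance_trigger_ratio``
    is the #pos/#neg ratio below which the log-likelihood fallback is
    fitted.  ``smoothing`` is the additive pseudo-count of the likelihood
    table.
    """

    width: int | None = None
    p_cutoff: float | None = 0.05
    imbalance_trigger_ratio: float = 2.0
    smoothing: float = 1.0
    value_heuristic_mode: str = "dominant-positive"  # or "max-difference"
    r_tie_break: str = "largest"  # or "smallest"
    include_priors: bool = True

    def __post_init__(self):
        if (self.width is None) == (self.p_cutoff is None):
            raise ValueError("set exactly one of width / p_cutoff")
        if self.width is not None and self.width < 1:
            raise ValueError("width must be >= 1")
        if self.imbalance_trigger_ratio <= 0:
            raise ValueError("imbalance_trigger_ratio must be positive")
        if self.value_heuristic_mode not in ("dominant-positive", "max-difference"):
            raise ValueError(f"unknown value heuristic {self.value_heuristic_mode!r}")
        if self.r_tie_break not in ("largest", "smallest"):
            raise ValueError(f"unknown tie break {self.r_tie_break!r}")


def _contingency(dataset: Dataset, target: TargetSpec, attribute: str):
    """2 x categories count table over non-MISSING cells; rows (T=t, T!=t)."""
    col = list(dataset.df[attribute])
    pos_mask = dataset.positive_mask(target)
    domain = dataset.domains[attribute]
    pos_counts = {v: 0 for v in domain}
    neg_counts = {v: 0 for v in domain}
    for cell, is_pos in zip(col, pos_mask):
        if cell is MISSING:
            continue
        (pos_counts if is_pos else neg_counts)[cell] += 1
    table = np.array(
        [[pos_counts[v] for v in domain], [neg_counts[v] for v in domain]],
        dtype=np.int64,
    )
    # drop all-zero columns (domain values never observed)
    keep = table.sum(axis=0) > 0
    return table[:, keep], tuple(v for v, k in zip(domain, keep) if k)


def chi_squared_select(
    dataset: Dataset, target: TargetSpec, config: DiscoveryConfig
) -> list[tuple[str, float, float]]:
    """Rank attributes by chi-squared association with the binarized target.

    Returns ``(attribute, statistic, p_value)`` triples sorted by ascending
    p-value (ties: descending statistic, then dataset attribute order),
    truncated to the top ``config.width`` or filtered at ``config.p_cutoff``.
    Single-category attributes get statistic 0 / p 1 and rank last; numeric
    attributes are rejected (categorize them first).
    """
    numerics = dataset.numeric_attributes
    if numerics:
        raise ValueError(
            f"raw numeric attributes {numerics} must be categorized before discovery"
        )
    classes = set(dataset.target_values(target))
    if len(classes) < 2:
        raise ValueError("need both positive and negative records")
    results = []
    for order, attr in enumerate(dataset.attributes):
        table, cats = _contingency(dataset, target, attr)
        if table.size == 0 or table.sum() == 0:
            log.warning("attribute %r has no observed values; excluded", attr)
            continue
        if table.shape[1] < 2 or table.sum(axis=1).min() == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p, dof, expected = chi2_contingency(table, correction=False)
            if expected.min() < 5:
                log.warning(
                    "attribute %r: expected count %.2f < 5 in chi-squared table",
                    attr,
                    expected.min(),
                )
        results.append((attr, float(stat), float(p), order))
    results.sort(key=lambda t: (t[2], -t[1], t[3]))
    ranked = [(a, s, p) for a, s, p, _ in results]
    if config.width is not None:
        return ranked[: config.width]
    return [t for t in ranked if t[2] <= config.p_cutoff]


def select_value(
    dataset: Dataset,
    target: TargetSpec,
    attribute: str,
    mode: str = "dominant-positive",
) -> str:
    """Pick the category of *attribute* most associated with T = t.

    Builds the two class-conditional percentage rows over non-missing cells
    and compares them column-wise.  ``dominant-positive`` (default): among
    categories where the positive percentage is at least the negative one,
    return the one maximizing the positive percentage (falling back to the
    global positive-row argmax when none qualifies).  ``max-difference``:
    return the category maximizing positive% - negative%.  Ties break by
    domain order.
    """
    table, cats = _contingency(dataset, target, attribute)
    if table.size == 0 or table[0].sum() == 0:
        raise ValueError(
            f"attribute {attribute!r}: no non-missing values among positives"
        )
    pos_row = table[0] / table[0].sum()
    neg_total = table[1].sum()
    neg_row = table[1] / neg_total if neg_total else np.zeros_like(pos_row)
    if mode == "max-difference":
        return cats[int(np.argmax(pos_row - neg_row))]
    if mode != "dominant-positive":
        raise ValueError(f"unknown value heuristic {mode!r}")
    dominant = pos_row >= neg_row
    if dominant.any():
        masked = np.where(dominant, pos_row, -np.inf)
        return cats[int(np.argmax(masked))]
    return cats[int(np.argmax(pos_row))]


def optimize_threshold(
    attrs: list[str],
    values: list[str],
    dataset: Dataset,
    target: TargetSpec,
    tie_break: str = "largest",
) -> tuple[float, float]:
    """Sweep r over {1/w, ..., w/w}; return (r, training G-mean) at the best.

    Ties in G-mean resolve to the largest r by default (strictest pattern,
    favoring specificity on unseen data) or smallest via *tie_break*.
    """
    w = len(attrs)
    if w < 1:
        raise ValueError("need at least one attribute")
    base = Pattern(attrs=tuple(attrs), values=tuple(values), r=1.0)
    counts = matched_counts(base, dataset)
    actual = dataset.positive_mask(target)
    best_r, best_g = None, -1.0
    for k in range(1, w + 1):
        predicted = counts >= k
        tp = int((predicted & actual).sum())
        fp = int((predicted & ~actual).sum())
        fn = int((~predicted & actual).sum())
        tn = int((~predicted & ~actual).sum())
        sen = tp / (tp + fn) if (tp + fn) else 0.0
        spec = tn / (tn + fp) if (tn + fp) else 0.0
        g = math.sqrt(sen * spec)
        better = g > best_g if tie_break == "smallest" else g >= best_g
        if better:
            best_r, best_g = k / w, g
    return best_r, best_g


@dataclass(frozen=True)
class LikelihoodTable:
    """Smoothed class-conditional log-probabilities over selected attributes.

    ``cond[attr][value]`` is ``(log P(value | T=t), log P(value | T!=t))``
    with additive smoothing over the attribute's category domain; values
    outside the domain score ``unseen[attr]``.  MISSING cells contribute
    nothing to a record's score.  Class log-priors come from training
    frequencies (can be zeroed for a pure-likelihood comparison).
    """

    cond: dict[str, dict[str, tuple[float, float]]]
    unseen: dict[str, tuple[float, float]]
    log_prior_pos: float
    log_prior_neg: float
    include_priors: bool = True

    def score(self, record: Record) -> tuple[float, float]:
        """(positive, negative) log scores of a record."""
        if self.include_priors:
            s_pos, s_neg = self.log_prior_pos, self.log_prior_neg
        else:
            s_pos = s_neg = 0.0
        for attr, table in self.cond.items():
            cell = record.values.get(attr, MISSING)
            if cell is MISSING:
                continue
            lp, ln = table.get(cell, self.unseen[attr])
            s_pos += lp
            s_neg += ln
        return s_pos, s_neg

    def to_dict(self) -> dict:
        return {
            "cond": {a: {v: list(p) for v, p in t.items()} for a, t in self.cond.items()},
            "unseen": {a: list(p) for a, p in self.unseen.items()},
            "log_prior_pos": self.log_prior_pos,
            "log_prior_neg": self.log_prior_neg,
            "include_priors": self.include_priors,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LikelihoodTable":
        return cls(
            cond={a: {v: tuple(p) for v, p in t.items()} for a, t in d["cond"].items()},
            unseen={a: tuple(p) for a, p in d["unseen"].items()},
            log_prior_pos=d["log_prior_pos"],
            log_prior_neg=d["log_prior_neg"],
            include_priors=d.get("include_priors", True),
        )


def fit_likelihoods(
    dataset: Dataset,
    target: TargetSpec,
    attrs: list[str],
    smoothing: float = 1.0,
    include_priors: bool = True,
) -> LikelihoodTable:
    """Additive-smoothed conditional probabilities per attribute and class.

    P(v | class) = (count + s) / (class_nonmissing_count + s * |domain|),
    counted over non-MISSING cells; an out-of-domain value at prediction
    time scores s / (class_nonmissing_count + s * |domain|).
    """
    prev = prevalence(dataset, target)
    if prev.n_positive == 0 or prev.n_negative == 0:
        raise ValueError("need both classes to fit likelihoods")
    pos_mask = dataset.positive_mask(target)
    cond: dict[str, dict[str, tuple[float, float]]] = {}
    unseen: dict[str, tuple[float, float]] = {}
    s = smoothing
    for attr in attrs:
        domain = dataset.domains[attr]
        col = list(dataset.df[attr])
        pos_counts = {v: 0 for v in domain}
        neg_counts = {v: 0 for v in domain}
        n_pos = n_neg = 0
        for cell, is_pos in zip(col, pos_mask):
            if cell is MISSING:
                continue
            if is_pos:
                pos_counts[cell] += 1
                n_pos += 1
            else:
                neg_counts[cell] += 1
                n_neg += 1
        denom_pos = n_pos + s * len(domain)
        denom_neg = n_neg + s * len(domain)
        cond[attr] = {
            v: (
                math.log((pos_counts[v] + s) / denom_pos),
                math.log((neg_counts[v] + s) / denom_neg),
            )
            for v in domain
        }
        unseen[attr] = (math.log(s / denom_pos), math.log(s / denom_neg))
    return LikelihoodTable(
        cond=cond,
        unseen=unseen,
        log_prior_pos=math.log(prev.n_positive / dataset.n),
        log_prior_neg=math.log(prev.n_negative / dataset.n),
        include_priors=include_priors,
    )


@dataclass(frozen=True)
class TrainedClassifier:
    pattern: Pattern
    likelihoods: LikelihoodTable | None
    config: DiscoveryConfig
    p_values: dict[str, float]
    training_g_mean: float

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "pattern": self.pattern.to_dict(),
            "pattern_line": self.pattern.to_line(),
            "likelihoods": self.likelihoods.to_dict() if self.likelihoods else None,
            "config": asdict(self.config),
            "p_values": self.p_values,
            "training_g_mean": self.training_g_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedClassifier":
        return cls(
            pattern=Pattern.from_dict(d["pattern"]),
            likelihoods=(
                LikelihoodTable.from_dict(d["likelihoods"]) if d["likelihoods"] else None
            ),
            config=DiscoveryConfig(**d["config"]),
            p_values=dict(d["p_values"]),
            training_g_mean=d["training_g_mean"],
        )


def train(
    dataset: Dataset, target: TargetSpec, config: DiscoveryConfig | None = None
) -> TrainedClassifier:
    """Full training pipeline: select attributes, values, threshold, fallback.

    The G-mean optimization runs on the training data only.  The likelihood
    table is fitted iff the training #pos/#neg ratio is below
    ``config.imbalance_trigger_ratio``.
    """
    config = config or DiscoveryConfig()
    selected = chi_squared_select(dataset, target, config)
    if not selected:
        raise ValueError(
            "no attribute passed the p-value cutoff; consider top-K selection "
            "(DiscoveryConfig(width=K, p_cutoff=None))"
        )
    attrs = [a for a, _, _ in selected]
    values = [
        select_value(dataset, target, a, mode=config.value_heuristic_mode)
        for a in attrs
    ]
    r, g = optimize_threshold(
        attrs, values, dataset, target, tie_break=config.r_tie_break
    )
    pat = Pattern(attrs=tuple(attrs), values=tuple(values), r=r)
    prev = prevalence(dataset, target)
    likelihoods = None
    if prev.ratio is not None and prev.ratio < config.imbalance_trigger_ratio:
        likelihoods = fit_likelihoods(
            dataset,
            target,
            attrs,
            smoothing=config.smoothing,
            include_priors=config.include_priors,
        )
    return TrainedClassifier(
        pattern=pat,
        likelihoods=likelihoods,
        config=config,
        p_values={a: p for a, _, p in selected},
        training_g_mean=g,
    )


def predict(clf: TrainedClassifier, record: Record) -> tuple[bool, dict]:
    """Classify one record; returns (is_positive, explanation).

    Positive iff the pattern matches OR (a likelihood table was fitted and
    the positive log score strictly exceeds the negative one; ties are
    negative).
    """
    matched, count = match(clf.pattern, record)
    explanation: dict = {"matched": matched, "matched_count": count}
    if matched:
        return True, explanation
    if clf.likelihoods is not None:
        s_pos, s_neg = clf.likelihoods.score(record)
        explanation["log_score_pos"] = s_pos
        explanation["log_score_neg"] = s_neg
        return s_pos > s_neg, explanation
    return False, explanation


def predict_dataset(clf: TrainedClassifier, dataset: Dataset) -> np.ndarray:
    """Vectorized predictions for every record of a dataset."""
    predicted = matched_counts(clf.pattern, dataset) >= clf.pattern.required_matches
    if clf.likelihoods is not None:
        lt = clf.likelihoods
        s_pos = np.full(dataset.n, lt.log_prior_pos if lt.include_priors else 0.0)
        s_neg = np.full(dataset.n, lt.log_prior_neg if lt.include_priors else 0.0)
        for attr, table in lt.cond.items():
            col = dataset.df[attr]
            lp = np.zeros(dataset.n)
            ln = np.zeros(dataset.n)
            for i, cell in enumerate(col):
                if cell is MISSING:
                    continue
                a, b = table.get(cell, lt.unseen[attr])
                lp[i] = a
                ln[i] = b
            s_pos += lp
            s_neg += ln
        predicted |= s_pos > s_neg
    return predicted
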