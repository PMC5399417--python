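"""Repeated stratified cross-validation with shared folds and up-sampling.

The evaluation protocol: 20 independent runs of stratified 10-fold
cross-validation.  Within a run every compared method is trained on the
same folds; the minority class may be up-sampled (duplication only) in the
training portion, while test folds are never touched, so test metrics
always reflect the original prevalence.  Each run yields one value per
metric (the mean over its k test folds); means and standard deviations are
reported over runs, and a one-sided paired Wilcoxon signed-rank test asks
whether pattern discovery's run-level values rank above each competitor's.

The Wilcoxon variant here is the normal approximation on the signed-rank
statistic WITHOUT continuity correction (zero differences dropped, average
ranks with the standard tie variance correction); the exact distribution
and the continuity-corrected approximation are available via flags.

A fair-coin random baseline (predict positive with probability 1/2) is
included: its theoretical sensitivity is 0.5 and its precision equals the
prevalence, giving closed-form reference F1 and G-mean at any prevalence.
"""

from __future__ import annotations

import csv
import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.stats import norm, rankdata, wilcoxon as _scipy_wilcoxon

from .data_model import Dataset, Record, TargetSpec, prevalence
from .discovery import DiscoveryConfig, predict_dataset, train
from .metrics import METRIC_NAMES, MetricSet, metrics_from_counts
from .pattern import ConfusionCounts

__all__ = [
    "CVPlan",
    "CVReport",
    "Comparator",
    "PatternDiscovery",
    "RandomBaseline",
    "SklearnComparator",
    "stratified_folds",
    "upsample_training",
    "run_experiment",
    "wilcoxon_one_sided_greater",
    "random_baseline_theoretical",
]


@dataclass(frozen=True)
class CVPlan:
    k: int = 10
    runs: int = 20
    seed: int = 0
    upsample_ratios: tuple = ("original",)

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("need k >= 2 folds")
        if self.runs < 1:
            raise ValueError("need at least one run")


@runtime_checkable
class Comparator(Protocol):
    """fit/predict contract every compared method implements.

    ``rng`` is passed at fit time so stochastic comparators (the random
    baseline) are reseeded identically across methods' shared folds;
    deterministic comparators ignore it.
    """

    name: str

    def fit(self, dataset: Dataset, target: TargetSpec, rng: np.random.Generator): ...

    def predict_many(self, dataset: Dataset) -> np.ndarray: ...


class PatternDiscovery:
    """The pattern-discovery classifier behind the comparator protocol."""

    def __init__(self, config: DiscoveryConfig | None = None, name: str = "pattern_discovery"):
        self.config = config
        self.name = name
        self.classifier = None

    def fit(self, dataset, target, rng=None):
        self.classifier = train(dataset, target, self.config)
        return self

    def predict_many(self, dataset):
        return predict_dataset(self.classifier, dataset)


class RandomBaseline:
    """Fair coin: positive with probability 1/2 for every record."""

    def __init__(self, name: str = "random_baseline"):
        self.name = name
        self._rng = np.random.default_rng(0)

    def fit(self, dataset, target, rng=None):
        if rng is not None:
            self._rng = rng
        return self

    def predict_many(self, dataset):
        return self._rng.random(dataset.n) < 0.5

    def predict(self, record: Record) -> bool:
        return bool(self._rng.random() < 0.5)


class SklearnComparator:
    """Adapter running a scikit-learn estimator on one-hot encoded cells.

    Missing cells encode as all-zeros in their attribute's block.  These
    comparators stand in for the conventional interpretable baselines
    (logistic regression, naive Bayes, decision tree); their third-party
    numerics are not a contract of this package.
    """

    def __init__(self, estimator, name: str):
        self.estimator = estimator
        self.name = name
        self._columns: list[tuple[str, str]] = []

    def _encode(self, dataset: Dataset) -> np.ndarray:
        from .data_model import MISSING

        X = np.zeros((dataset.n, len(self._columns)))
        index = {pair: j for j, pair in enumerate(self._columns)}
        for i in range(dataset.n):
            row = dataset.df.iloc[i]
            for attr in {a for a, _ in self._columns}:
                v = row[attr]
                if v is MISSING:
                    continue
                j = index.get((attr, v))
                if j is not None:
                    X[i, j] = 1.0
        return X

    def fit(self, dataset, target, rng=None):
        import sklearn.base

        self._columns = [
            (attr, v) for attr in dataset.attributes for v in dataset.domains[attr]
        ]
        y = dataset.positive_mask(target).astype(int)
        self.estimator = sklearn.base.clone(self.estimator)
        self.estimator.fit(self._encode(dataset), y)
        return self

    def predict_many(self, dataset):
        return self.estimator.predict(self._encode(dataset)).astype(bool)


def default_comparators(config: DiscoveryConfig | None = None) -> list:
    """Pattern discovery, the fair-coin baseline, and the three conventional
    interpretable methods at library defaults."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB
    from sklearn.tree import DecisionTreeClassifier

    return [
        PatternDiscovery(config),
        RandomBaseline(),
        SklearnComparator(LogisticRegression(max_iter=1000), "logistic_regression"),
        SklearnComparator(BernoulliNB(), "naive_bayes"),
        SklearnComparator(DecisionTreeClassifier(random_state=0), "decision_tree"),
    ]


# ---------------------------------------------------------------------------
# Folds and up-sampling


def stratified_folds(
    dataset: Dataset, target: TargetSpec, k: int, rng_seed: int
) -> list[np.ndarray]:
    """k disjoint index sets with per-fold positive counts within 1.

    Each class is shuffled (seed-driven) and dealt round-robin, so fold
    positive counts differ by at most one; k may be as large as n (the
    leave-one-out degenerate case where every fold has a single record).
    """
    if not 2 <= k <= dataset.n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={dataset.n}")
    rng = np.random.default_rng(rng_seed)
    pos_mask = dataset.positive_mask(target)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = 0
    for mask in (pos_mask, ~pos_mask):
        idx = np.flatnonzero(mask)
        rng.shuffle(idx)
        for i in idx:
            folds[cursor % k].append(int(i))
            cursor += 1
    return [np.array(sorted(f), dtype=int) for f in folds]


def upsample_training(
    dataset: Dataset, target: TargetSpec, ratio, rng_seed: int
) -> Dataset:
    """Duplicate minority positives until #pos/#neg first reaches *ratio*.

    Appended records are uniform-with-replacement copies of existing
    positives; negatives and all original records are untouched, and no
    synthetic values are generated.  ``ratio="original"`` is a no-op.
    """
    if ratio == "original":
        return dataset
    prev = prevalence(dataset, target)
    if prev.n_negative == 0:
        raise ValueError("no negatives; ratio undefined")
    current = prev.n_positive / prev.n_negative
    if ratio < current - 1e-12:
        raise ValueError(
            f"ratio {ratio} below current {current:.3f}; down-sampling unsupported"
        )
    target_pos = math.ceil(ratio * prev.n_negative)
    n_extra = max(0, target_pos - prev.n_positive)
    if n_extra == 0:
        return dataset
    rng = np.random.default_rng(rng_seed)
    pos_idx = np.flatnonzero(dataset.positive_mask(target))
    extra = rng.choice(pos_idx, size=n_extra, replace=True)
    all_idx = np.concatenate([np.arange(dataset.n), extra])
    return dataset.subset(all_idx)


# ---------------------------------------------------------------------------
# Wilcoxon


def wilcoxon_one_sided_greater(
    a: Sequence[float],
    b: Sequence[float],
    continuity_correction: bool = False,
    exact: bool = False,
) -> float:
    """One-sided paired Wilcoxon signed-rank p-value for "a > b".

    Zero differences are dropped before ranking; ties receive average ranks
    with the standard variance tie-correction.  The default is the normal
    approximation without continuity correction; flags switch on the
    correction or the exact distribution (tie-free small samples).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise ValueError("need two equal-length 1-D samples")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("no non-zero differences")
    if exact:
        return float(
            _scipy_wilcoxon(d, alternative="greater", method="exact").pvalue
        )
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    n = len(d)
    mu = n * (n + 1) / 4
    var = n * (n + 1) * (2 * n + 1) / 24
    # tie correction: subtract sum(t^3 - t)/48 over tied groups of |d|
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts**3 - counts).sum() / 48
    if var <= 0:
        raise ValueError("zero variance after tie correction")
    num = w_plus - mu
    if continuity_correction and num != 0:
        num -= 0.5 * np.sign(num)
    return float(norm.sf(num / math.sqrt(var)))


def random_baseline_theoretical(prev: float) -> dict[str, float]:
    """Closed-form fair-coin metrics at a given prevalence."""
    sen = spec = 0.5
    pre = prev
    f1 = 2 * pre * sen / (pre + sen) if pre + sen else 0.0
    return {
        "precision": pre,
        "sensitivity": sen,
        "specificity": spec,
        "f1": f1,
        "g_mean": math.sqrt(sen * spec),
    }


# ---------------------------------------------------------------------------
# The experiment


@dataclass
class CVReport:
    """Run-level metric values per (method, ratio), with summaries.

    ``values[(method, ratio, metric)]`` is the array of per-run values (one
    value per run = the mean over that run's k test folds).
    """

    methods: list[str]
    ratios: list
    runs: int
    values: dict[tuple, np.ndarray]
    wilcoxon: dict[tuple, float] = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)
    reference_method: str = "pattern_discovery"

    def mean(self, method, ratio, metric) -> float:
        return float(np.mean(self.values[(method, ratio, metric)]))

    def sd(self, method, ratio, metric) -> float:
        return float(np.std(self.values[(method, ratio, metric)], ddof=1))

    def summary_rows(self) -> list[dict]:
        rows = []
        for method in self.methods:
            for ratio in self.ratios:
                row = {"method": method, "ratio": ratio}
                for metric in METRIC_NAMES:
                    row[f"{metric}_mean"] = self.mean(method, ratio, metric)
                    row[f"{metric}_sd"] = self.sd(method, ratio, metric)
                    p = self.wilcoxon.get((method, ratio, metric))
                    if p is not None:
                        row[f"{metric}_wilcoxon_p"] = p
                rows.append(row)
        return rows

    def to_json(self, path) -> None:
        doc = {
            "methods": self.methods,
            "ratios": [str(r) for r in self.ratios],
            "runs": self.runs,
            "values": {
                f"{m}|{r}|{metric}": list(map(float, v))
                for (m, r, metric), v in self.values.items()
            },
            "wilcoxon": {
                f"{m}|{r}|{metric}": float(p)
                for (m, r, metric), p in self.wilcoxon.items()
            },
            "failures": self.failures,
            "summary": self.summary_rows(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=str)

    def to_csv(self, path) -> None:
        """Flat table: method, ratio, metric, run, value."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["method", "ratio", "metric", "run", "value"])
            for (method, ratio, metric), vals in self.values.items():
                for run, v in enumerate(vals):
                    w.writerow([method, ratio, metric, run, f"{v:.6f}"])


def run_experiment(
    dataset: Dataset,
    target: TargetSpec,
    comparators: Sequence,
    plan: CVPlan,
) -> CVReport:
    """The full protocol: shared folds, training-only up-sampling, Wilcoxon.

    Per run: one seeded fold assignment shared by every comparator; per fold
    and up-sampling ratio the training portion is up-sampled, the model fit,
    and the untouched test fold scored.  A comparator failure on a fold is
    recorded in ``report.failures`` (the run-level value becomes NaN), never
    silently skipped.
    """
    if not comparators:
        raise ValueError("need at least one comparator")
    names = [c.name for c in comparators]
    if len(set(names)) != len(names):
        raise ValueError("comparator names must be unique")
    ss = np.random.SeedSequence(plan.seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(plan.runs)]
    values: dict[tuple, list] = {
        (name, ratio, metric): []
        for name in names
        for ratio in plan.upsample_ratios
        for metric in METRIC_NAMES
    }
    failures: list[dict] = []
    for run, run_seed in enumerate(run_seeds):
        folds = stratified_folds(dataset, target, plan.k, run_seed)
        all_idx = np.arange(dataset.n)
        for ratio in plan.upsample_ratios:
            fold_metrics: dict[str, list[MetricSet]] = {name: [] for name in names}
            for fold_no, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(all_idx, test_idx)
                train_ds = dataset.subset(train_idx)
                test_ds = dataset.subset(test_idx)
                up_seed = (run_seed + 7919 * fold_no) % (2**31)
                train_up = upsample_training(train_ds, target, ratio, up_seed)
                actual = test_ds.positive_mask(target)
                for comp in comparators:
                    # crc32: stable across processes, unlike builtin str hash
                    rng = np.random.default_rng(
                        (up_seed + zlib.crc32(comp.name.encode())) % (2**31)
                    )
                    try:
                        comp.fit(train_up, target, rng)
                        predicted = np.asarray(comp.predict_many(test_ds), dtype=bool)
                        c = ConfusionCounts(
                            TP=int((predicted & actual).sum()),
                            FP=int((predicted & ~actual).sum()),
                            TN=int((~predicted & ~actual).sum()),
                            FN=int((~predicted & actual).sum()),
                        )
                        fold_metrics[comp.name].append(metrics_from_counts(c))
                    except Exception as e:  # recorded, not silently dropped
                        failures.append(
                            {
                                "method": comp.name,
                                "run": run,
                                "fold": fold_no,
                                "ratio": str(ratio),
                                "error": repr(e),
                            }
                        )
            for name in names:
                ms = fold_metrics[name]
                for metric in METRIC_NAMES:
                    if len(ms) == len(folds):
                        v = float(np.mean([getattr(m, metric) for m in ms]))
                    else:
                        v = float("nan")
                    values[(name, ratio, metric)].append(v)
    report = CVReport(
        methods=names,
        ratios=list(plan.upsample_ratios),
        runs=plan.runs,
        values={k: np.array(v) for k, v in values.items()},
        failures=failures,
    )
    ref = report.reference_method
    if ref in names and len(names) > 1:
        for name in names:
            if name == ref:
                continue
            for ratio in plan.upsample_ratios:
                for metric in METRIC_NAMES:
                    a = report.values[(ref, ratio, metric)]
                    b = report.values[(name, ratio, metric)]
                    try:
                        report.wilcoxon[(name, ratio, metric)] = (
                            wilcoxon_one_sided_greater(a, b)
                        )
                    except ValueError:
                        pass  # all-zero differences: no test available
    return report
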