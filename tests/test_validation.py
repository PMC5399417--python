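import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import norm, wilcoxon as scipy_wilcoxon

from patdisc import (
    CVPlan,
    DiscoveryConfig,
    PatternDiscovery,
    RandomBaseline,
    SyntheticSpec,
    TargetSpec,
    generate,
    prevalence,
    random_baseline_theoretical,
    run_experiment,
    stratified_folds,
    upsample_training,
    wilcoxon_one_sided_greater,
)


@pytest.fixture(scope="module")
def imbalanced():
    spec = SyntheticSpec(n=470, prevalence=70 / 470, seed=17, missing_rate=0.0)
    ds, _ = generate(spec)
    return ds, spec.target


class TestStratifiedFolds:
    def test_partition_and_positive_balance(self, imbalanced):
        ds, target = imbalanced
        folds = stratified_folds(ds, target, k=10, rng_seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(ds.n))
        pos = ds.positive_mask(target)
        # 70 positives over 10 folds: exactly 7 each, 47 records per fold
        assert [int(pos[f].sum()) for f in folds] == [7] * 10
        assert [len(f) for f in folds] == [47] * 10

    def test_positive_counts_within_one_generally(self, imbalanced):
        ds, target = imbalanced
        pos = ds.positive_mask(target)
        for k in (3, 7, 9):
            folds = stratified_folds(ds, target, k=k, rng_seed=1)
            counts = [int(pos[f].sum()) for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_agrees_with_sklearn_stratification_balance(self, imbalanced):
        """Independent check: sklearn's stratified splitter yields the same
        per-fold positive counts (as a multiset)."""
        from sklearn.model_selection import StratifiedKFold

        ds, target = imbalanced
        pos = ds.positive_mask(target)
        ours = sorted(
            int(pos[f].sum()) for f in stratified_folds(ds, target, 10, 0)
        )
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        theirs = sorted(
            int(pos[test].sum()) for _, test in skf.split(np.zeros(ds.n), pos)
        )
        assert ours == theirs

    def test_leave_one_out_degenerate(self, table1, bleeding):
        folds = stratified_folds(table1, bleeding, k=table1.n, rng_seed=0)
        assert [len(f) for f in folds] == [1] * table1.n

    def test_determinism(self, imbalanced):
        ds, target = imbalanced
        a = stratified_folds(ds, target, 10, rng_seed=42)
        b = stratified_folds(ds, target, 10, rng_seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_out_of_range_rejected(self, table1, bleeding):
        with pytest.raises(ValueError):
            stratified_folds(table1, bleeding, k=7, rng_seed=0)
        with pytest.raises(ValueError):
            stratified_folds(table1, bleeding, k=1, rng_seed=0)


class TestUpsample:
    def _tiny(self, n_pos=10, n_neg=100):
        spec = SyntheticSpec(
            n=n_pos + n_neg, prevalence=n_pos / (n_pos + n_neg), seed=23,
            missing_rate=0.0,
        )
        return generate(spec)[0], spec.target

    def test_ratio_half_yields_fifty_positives(self):
        ds, target = self._tiny()
        up = upsample_training(ds, target, ratio=0.5, rng_seed=0)
        prev = prevalence(up, target)
        assert prev.n_positive == 50 and prev.n_negative == 100

    def test_current_ratio_is_identity(self):
        ds, target = self._tiny()
        assert upsample_training(ds, target, ratio=0.1, rng_seed=0) == ds
        assert upsample_training(ds, target, "original", rng_seed=0) == ds

    def test_appended_records_duplicate_existing_positives(self):
        ds, target = self._tiny()
        up = upsample_training(ds, target, ratio=0.4, rng_seed=3)
        originals = {
            tuple(ds.df.iloc[i]) for i in np.flatnonzero(ds.positive_mask(target))
        }
        for i in range(ds.n, up.n):
            assert tuple(up.df.iloc[i]) in originals

    def test_negative_multiset_conserved(self):
        ds, target = self._tiny()
        up = upsample_training(ds, target, ratio=0.8, rng_seed=1)
        neg_before = Counter(
            tuple(ds.df.iloc[i]) for i in np.flatnonzero(~ds.positive_mask(target))
        )
        neg_after = Counter(
            tuple(up.df.iloc[i]) for i in np.flatnonzero(~up.positive_mask(target))
        )
        assert neg_before == neg_after

    def test_downsampling_rejected(self):
        ds, target = self._tiny()
        with pytest.raises(ValueError, match="down-sampling"):
            upsample_training(ds, target, ratio=0.05, rng_seed=0)


class TestWilcoxon:
    def test_all_positive_distinct_closed_form(self):
        for n in range(5, 31):
            a = np.arange(1.0, n + 1)
            p = wilcoxon_one_sided_greater(a, np.zeros(n))
            mu = n * (n + 1) / 4
            sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24)
            assert p == pytest.approx(norm.sf(mu / sd), rel=1e-12)

    def test_swapped_samples_complementary(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(20), rng.random(20)
        p = wilcoxon_one_sided_greater(a, b)
        assert wilcoxon_one_sided_greater(b, a) == pytest.approx(1 - p)

    def test_antisymmetric_differences_null(self):
        a = np.array([1.0, 2.0] * 10)
        b = np.array([2.0, 1.0] * 10)
        assert wilcoxon_one_sided_greater(a, b) == pytest.approx(0.5)

    def test_all_zero_differences_is_error(self):
        with pytest.raises(ValueError, match="non-zero"):
            wilcoxon_one_sided_greater([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped(self):
        # pairs with equal values must not contribute ranks
        a = [5.0, 1.0, 2.0, 3.0]
        b = [5.0, 0.0, 0.0, 0.0]
        expected = wilcoxon_one_sided_greater([1.0, 2.0, 3.0], [0.0] * 3)
        assert wilcoxon_one_sided_greater(a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_check_against_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 5, size=20).astype(float)
        b = rng.integers(0, 5, size=20).astype(float)
        if np.all(a == b):
            pytest.skip("degenerate draw")
        ours = wilcoxon_one_sided_greater(a, b)
        ref = scipy_wilcoxon(
            a, b, alternative="greater", method="approx", correction=False,
            zero_method="wilcox",
        ).pvalue
        assert ours == pytest.approx(float(ref), rel=1e-9)

    def test_continuity_correction_flag(self):
        a = np.arange(1.0, 21)
        p_corr = wilcoxon_one_sided_greater(a, np.zeros(20), continuity_correction=True)
        ref = scipy_wilcoxon(
            a, alternative="greater", method="approx", correction=True
        ).pvalue
        assert p_corr == pytest.approx(float(ref), rel=1e-9)

    def test_exact_flag_small_sample(self):
        a = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
        p = wilcoxon_one_sided_greater(a, np.zeros(5), exact=True)
        assert p == pytest.approx(1 / 32)


class TestRandomBaseline:
    def test_seeded_draw_concentrates_at_half(self):
        rb = RandomBaseline()
        rb.fit(None, None, np.random.default_rng(5))
        draws = np.array([rb.predict(None) for _ in range(100_000)])
        assert abs(draws.mean() - 0.5) < 3 * math.sqrt(0.25 / 100_000) + 0.002

    def test_same_seed_same_sequence(self):
        seqs = []
        for _ in range(2):
            rb = RandomBaseline()
            rb.fit(None, None, np.random.default_rng(9))
            seqs.append([rb.predict(None) for _ in range(50)])
        assert seqs[0] == seqs[1]

    def test_theoretical_metrics_at_prevalence(self):
        ref = random_baseline_theoretical(0.149)
        assert ref["sensitivity"] == 0.5
        assert ref["precision"] == 0.149
        assert round(ref["f1"], 2) == 0.23


@pytest.fixture(scope="module")
def small():
    spec = SyntheticSpec(n=120, prevalence=0.15, seed=31, n_noise_attrs=4)
    ds, _ = generate(spec)
    return ds, spec.target


class TestRunExperiment:
    def test_report_shape_single_run(self, small):
        ds, target = small
        plan = CVPlan(k=2, runs=1, seed=0)
        report = run_experiment(ds, target, [RandomBaseline()], plan)
        for metric in ("precision", "sensitivity", "f1", "g_mean"):
            assert len(report.values[("random_baseline", "original", metric)]) == 1
        assert report.wilcoxon == {}  # single comparator: nothing to compare

    def test_baseline_converges_to_theory(self, small):
        ds, target = small
        plan = CVPlan(k=5, runs=20, seed=3)
        report = run_experiment(ds, target, [RandomBaseline()], plan)
        prev = prevalence(ds, target).prevalence
        for metric, theory in (("sensitivity", 0.5), ("precision", prev)):
            vals = report.values[("random_baseline", "original", metric)]
            se = vals.std(ddof=1) / math.sqrt(len(vals))
            assert abs(vals.mean() - theory) < 3 * se + 1e-9

    def test_folds_shared_and_tests_never_upsampled(self, small):
        """Every record appears in exactly one test fold per run, at every
        up-sampling ratio: the test multiset is the original dataset."""
        ds, target = small
        seen: dict[tuple, list] = {}

        class Spy:
            name = "spy"

            def fit(self, dataset, t, rng=None):
                self.n_train = dataset.n
                return self

            def predict_many(self, dataset):
                key = tuple(map(tuple, dataset.df.itertuples(index=False)))
                seen.setdefault(key, []).append(self.n_train)
                return np.zeros(dataset.n, dtype=bool)

        plan = CVPlan(k=4, runs=2, seed=1, upsample_ratios=("original", 0.5))
        run_experiment(ds, target, [Spy()], plan)
        total_test_records = Counter()
        for key, trains in seen.items():
            for _ in trains:
                total_test_records.update(key)
        original = Counter(map(tuple, ds.df.itertuples(index=False)))
        runs_times_ratios = 2 * 2
        assert total_test_records == Counter(
            {k: v * runs_times_ratios for k, v in original.items()}
        )

    def test_upsampling_grows_training_only(self, small):
        ds, target = small

        sizes = {}

        class Probe:
            name = "probe"

            def fit(self, dataset, t, rng=None):
                sizes.setdefault("train", []).append(dataset.n)
                return self

            def predict_many(self, dataset):
                sizes.setdefault("test", []).append(dataset.n)
                return np.zeros(dataset.n, dtype=bool)

        plan = CVPlan(k=4, runs=1, seed=1, upsample_ratios=(0.5,))
        run_experiment(ds, target, [Probe()], plan)
        assert all(n > ds.n * 3 / 4 for n in sizes["train"])  # positives added
        assert sum(sizes["test"]) == ds.n

    def test_comparator_failure_recorded_not_skipped(self, small):
        ds, target = small

        class Broken:
            name = "broken"

            def fit(self, dataset, t, rng=None):
                raise RuntimeError("boom")

            def predict_many(self, dataset):  # pragma: no cover
                return np.zeros(dataset.n, dtype=bool)

        plan = CVPlan(k=3, runs=1, seed=0)
        report = run_experiment(ds, target, [Broken()], plan)
        assert len(report.failures) == 3
        assert math.isnan(report.values[("broken", "original", "f1")][0])

    def test_wilcoxon_columns_with_two_comparators(self, small):
        ds, target = small
        plan = CVPlan(k=3, runs=6, seed=2)
        comps = [PatternDiscovery(DiscoveryConfig(width=4, p_cutoff=None)), RandomBaseline()]
        report = run_experiment(ds, target, comps, plan)
        key = ("random_baseline", "original", "g_mean")
        assert key in report.wilcoxon and 0 <= report.wilcoxon[key] <= 1

    def test_report_files(self, small, tmp_path):
        ds, target = small
        plan = CVPlan(k=3, runs=2, seed=2)
        report = run_experiment(ds, target, [RandomBaseline()], plan)
        report.to_json(tmp_path / "r.json")
        report.to_csv(tmp_path / "r.csv")
        import csv as _csv
        import json as _json

        doc = _json.loads((tmp_path / "r.json").read_text())
        assert doc["runs"] == 2 and doc["methods"] == ["random_baseline"]
        rows = list(_csv.DictReader(open(tmp_path / "r.csv")))
        # 1 method x 1 ratio x 5 metrics x 2 runs
        assert len(rows) == 10
        assert set(rows[0]) == {"method", "ratio", "metric", "run", "value"}
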