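import numpy as np
import pytest

from nanoreadacross import (
    PredictionRecord,
    SyntheticConfig,
    compare_experiments,
    generate_dataset,
    pi_coverage,
    r_squared,
    repeated_kfold_cv,
    rmse,
)
from nanoreadacross.validation import coefficient_of_determination, cv_runs_frame

ENDPOINT = "net_cell_association"


@pytest.fixture(scope="module")
def small_dataset():
    ds, _ = generate_dataset(SyntheticConfig(n_substances=40, seed=5))
    return ds


class TestMetrics:
    def test_rmse_examples(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1, -1], [0, 0]) == 1.0
        assert rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])

    def test_r2_identity_and_affine_invariance(self, rng):
        m = rng.standard_normal(30)
        assert r_squared(m, m) == pytest.approx(1.0)
        assert r_squared(3.0 * m + 2.0, m) == pytest.approx(1.0)

    def test_r2_constant_vector_undefined(self):
        assert r_squared([1.0, 1.0, 1.0], [1, 2, 3]) is None

    def test_r2_independent_vectors_near_zero(self, rng):
        a, b = rng.standard_normal(3000), rng.standard_normal(3000)
        assert r_squared(a, b) < 0.01

    def test_coefficient_of_determination_differs_from_pearson_sq(self):
        meas = [0.0, 1.0, 2.0, 3.0]
        pred = [10.0, 11.0, 12.0, 13.0]  # perfectly correlated, badly located
        assert r_squared(pred, meas) == pytest.approx(1.0)
        assert coefficient_of_determination(pred, meas) < 0

    def test_pi_coverage_examples(self):
        def rec(qid, lo, hi):
            v = (lo + hi) / 2
            return PredictionRecord(query_id=qid, endpoint="e", value=v,
                                    interval_low=lo, interval_high=hi,
                                    algorithm_used="RF")

        meas = {f"q{i}": 0.0 for i in range(20)}
        inside = [rec(f"q{i}", -1, 1) for i in range(19)]
        outside = [rec("q19", 5, 7)]
        assert pi_coverage(inside + outside, meas) == 95.0
        assert pi_coverage(inside, meas) == 100.0
        assert pi_coverage(outside, {"q19": 0.0}) == 0.0

    def test_pi_coverage_requires_intervals(self):
        rec = PredictionRecord(query_id="q", endpoint="e", value=1.0, algorithm_used="WA")
        with pytest.raises(ValueError):
            pi_coverage([rec], {"q": 1.0})


class TestRepeatedKFoldCV:
    def test_each_substance_tested_exactly_once_per_repeat(self, small_dataset):
        runs = repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA",
                                 k=5, repeats=2, seed=1)
        assert len(runs) == 2
        for run in runs:
            tested = [r.query_id for r in run.predictions]
            assert sorted(tested) == sorted(small_dataset.ids)
            assert set(run.fold_assignments.values()) == set(range(5))
            assert run.n_predicted + run.n_out_of_domain == len(small_dataset)

    def test_fixed_seed_reproduces_wa_metrics_exactly(self, small_dataset):
        a = repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA", k=5, repeats=2, seed=9)
        b = repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA", k=5, repeats=2, seed=9)
        assert [r.fold_assignments for r in a] == [r.fold_assignments for r in b]
        assert [r.rmse for r in a] == [r.rmse for r in b]
        assert [r.r2 for r in a] == [r.r2 for r in b]

    def test_wa_runs_have_no_coverage(self, small_dataset):
        runs = repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA", k=5, repeats=1, seed=2)
        assert runs[0].pi_coverage is None

    def test_k_larger_than_n_errors(self, small_dataset):
        with pytest.raises(ValueError):
            repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA", k=99, repeats=1)

    def test_unknown_endpoint_errors(self, small_dataset):
        with pytest.raises(Exception):
            repeated_kfold_cv(small_dataset, "nope", "P-CHEM", "WA", k=5)

    def test_tidy_frame_one_row_per_repeat(self, small_dataset):
        runs = repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA", k=5, repeats=3, seed=3)
        frame = cv_runs_frame(runs)
        assert len(frame) == 3
        assert {"rmse", "r2", "pi_coverage", "n_out_of_domain"} <= set(frame.columns)


class TestNoLeakageByConstruction:
    def test_test_fold_feature_values_cannot_change_fold_mates(self, small_dataset):
        """Perturbing one substance's features must not move predictions of the
        other substances in its own test fold (they share a training split that
        excludes the perturbed substance entirely)."""
        seed = 123
        runs = repeated_kfold_cv(small_dataset, ENDPOINT, "P-CHEM", "WA",
                                 k=5, repeats=1, seed=seed)
        target = small_dataset.ids[0]
        fold = runs[0].fold_assignments[target]
        mates = [i for i, f in runs[0].fold_assignments.items() if f == fold and i != target]

        import copy
        mutated = copy.deepcopy(small_dataset)
        sub = mutated.substance(target)
        for f in list(sub.properties):
            sub.properties[f] = sub.properties[f] * 100.0 + 7.0
        runs2 = repeated_kfold_cv(mutated, ENDPOINT, "P-CHEM", "WA",
                                  k=5, repeats=1, seed=seed)
        assert runs2[0].fold_assignments == runs[0].fold_assignments
        before = {r.query_id: r.value for r in runs[0].predictions}
        after = {r.query_id: r.value for r in runs2[0].predictions}
        for mate in mates:
            assert after[mate] == before[mate]


class TestCompareExperiments:
    def test_separated_groups_flagged_significant(self):
        a = [1.5 + d for d in (-0.04, -0.02, 0.0, 0.02, 0.04)]  # sd ~0.03
        b = [2.1 + d for d in (-0.04, -0.02, 0.0, 0.02, 0.04)]
        report = compare_experiments({"A": a, "B": b}, metric="rmse")
        assert report.anova_p < 1e-6
        assert report.significant_pairs() == [("A", "B")]
        row = report.tukey.iloc[0]
        assert abs(row.meandiff) == pytest.approx(0.6)

    def test_identical_groups_not_significant(self):
        vals = [1.0, 1.1, 0.9, 1.05, 0.95]
        report = compare_experiments({"A": vals, "B": list(vals)}, metric="r2")
        assert report.anova_p == pytest.approx(1.0)
        assert report.significant_pairs() == []

    def test_identical_constant_groups_handled(self):
        report = compare_experiments({"A": [1.0, 1.0], "B": [1.0, 1.0]})
        assert report.anova_f == 0.0 and report.anova_p == 1.0
        assert not report.tukey.significant.any()

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            compare_experiments({"A": [1, 2, 3]})

    def test_three_groups_cover_all_pairs_once(self):
        report = compare_experiments(
            {"A": [1.0, 1.1, 1.2], "B": [2.0, 2.1, 2.2], "C": [3.0, 3.1, 3.2]}
        )
        pairs = {tuple(sorted(p)) for p in zip(report.tukey.group1, report.tukey.group2)}
        assert pairs == {("A", "B"), ("A", "C"), ("B", "C")}
        assert len(report.tukey) == 3
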