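import numpy as np
import pytest

from nanoreadacross import (
    Dataset,
    LocalModelConfig,
    Neighbor,
    RelevantFeatureSet,
    Substance,
    build_model,
    find_neighbors,
    fit_local_model,
    predict,
    prediction_interval,
    weighted_average,
)
from nanoreadacross.feature_selection import FeatureStats
import nanoreadacross.local_models as lm

ENDPOINT = "tox"


def quant_bundle(vectors, activities, algorithm="WA", threshold=None, seed=0):
    """Bundle over two unit-scaled features with hand-set training vectors."""
    rfs = RelevantFeatureSet(
        endpoint=ENDPOINT, alpha=0.05,
        stats=[FeatureStats("f1", 1.0, 0.0, 10, 0.0, 1.0),
               FeatureStats("f2", 1.0, 0.0, 10, 0.0, 1.0)],
    )
    substances = [
        Substance(id=k, properties={"f1": v[0], "f2": v[1]}, endpoints={ENDPOINT: a})
        for (k, v), a in zip(vectors.items(), activities)
    ]
    ds = Dataset(substances, ["f1", "f2"], [ENDPOINT])
    return build_model(ds, ENDPOINT, "P-CHEM", algorithm, relevant=rfs,
                       sim_threshold=threshold,
                       model_config=LocalModelConfig(algorithm=algorithm, seed=seed))


def query(x1, x2, qid="Q"):
    return Substance(id=qid, properties={"f1": x1, "f2": x2})


class TestWeightedAverage:
    @pytest.mark.parametrize(
        "acts, sims, expected",
        [([2, 4], [0.5, 0.5], 3.0), ([0, 10], [0.9, 0.1], 1.0), ([7.3], [0.42], 7.3)],
    )
    def test_closed_form(self, acts, sims, expected):
        nbrs = [Neighbor(f"n{i}", s, a) for i, (s, a) in enumerate(zip(sims, acts))]
        assert weighted_average(nbrs) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            weighted_average([])

    def test_convex_combination_property(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 10))
            acts = rng.normal(0, 3, k)
            sims = rng.uniform(0.01, 1.0, k)
            wa = weighted_average(
                [Neighbor(f"n{i}", s, a) for i, (s, a) in enumerate(zip(sims, acts))]
            )
            assert acts.min() - 1e-12 <= wa <= acts.max() + 1e-12


class TestPredictionInterval:
    @pytest.mark.parametrize("rmse_in, expected", [(2.0, 3.92), (0.0, 0.0), (1.0, 1.96)])
    def test_halfwidth(self, rmse_in, expected):
        assert prediction_interval(rmse_in) == pytest.approx(expected)

    def test_negative_rmse_errors(self):
        with pytest.raises(ValueError):
            prediction_interval(-0.1)

    def test_monotone_in_rmse(self):
        grid = np.linspace(0, 5, 20)
        widths = [prediction_interval(r) for r in grid]
        assert all(b >= a for a, b in zip(widths, widths[1:]))


class TestFindNeighbors:
    def test_threshold_filter_keeps_two_of_three(self):
        # cosine with the query (1, 0) is just the first coordinate of a unit vector
        def unit(c):
            return (c, np.sqrt(1 - c * c))

        bundle = quant_bundle(
            {"a": unit(0.6), "b": unit(0.55), "c": unit(0.4)}, [1.0, 2.0, 3.0],
            threshold=0.5,
        )
        nbrs = find_neighbors(query(1.0, 0.0), bundle)
        assert [n.substance_id for n in nbrs] == ["a", "b"]
        assert nbrs[0].similarity == pytest.approx(0.6)

    def test_all_below_threshold_is_empty(self):
        bundle = quant_bundle({"a": (0.0, 1.0)}, [1.0], threshold=0.5)
        assert find_neighbors(query(1.0, 0.0), bundle) == []

    def test_exact_duplicate_is_eliminated(self):
        bundle = quant_bundle(
            {"dup": (1.0, 0.0), "other": (0.9, np.sqrt(1 - 0.81))}, [5.0, 1.0],
            threshold=0.5,
        )
        nbrs = find_neighbors(query(1.0, 0.0), bundle)
        assert [n.substance_id for n in nbrs] == ["other"]

    def test_query_own_id_excluded(self):
        bundle = quant_bundle({"Q": (0.9, 0.1), "n": (0.95, 0.05)}, [5.0, 1.0])
        assert [n.substance_id for n in find_neighbors(query(1.0, 0.0), bundle)] == ["n"]

    def test_sorted_by_descending_similarity_then_id(self):
        c = (0.8, np.sqrt(1 - 0.64))
        bundle = quant_bundle({"b": c, "a": c, "z": (0.99, np.sqrt(1 - 0.9801))},
                              [1, 2, 3], threshold=0.5)
        assert [n.substance_id for n in find_neighbors(query(1.0, 0.0), bundle)] == ["z", "a", "b"]

    def test_binary_duplicate_fingerprint_eliminated(self):
        subs = [
            Substance(id="dup", core_smiles="[Au]", coating_smiles=["CCO"],
                      endpoints={ENDPOINT: 9.0}),
            Substance(id="near", core_smiles="[Au]", coating_smiles=["CCS"],
                      endpoints={ENDPOINT: 1.0}),
        ]
        ds = Dataset(subs, [], [ENDPOINT])
        bundle = build_model(ds, ENDPOINT, "MP2D", "WA")
        q = Substance(id="Q", core_smiles="[Au]", coating_smiles=["CCO"])
        nbrs = find_neighbors(q, bundle)
        assert [n.substance_id for n in nbrs] == ["near"]


class TestFitLocalModel:
    def _neighbors(self, n, rng, noise=0.0):
        X = rng.standard_normal((n, 2))
        y = 2.0 * X[:, 0] + noise * rng.standard_normal(n)
        nbrs = [Neighbor(f"n{i}", float(rng.uniform(0.5, 1.0)), float(y[i]))
                for i in range(n)]
        return nbrs, X

    def test_constant_activities_fall_back_to_wa(self, rng):
        nbrs = [Neighbor(f"n{i}", 0.8, 4.2) for i in range(10)]
        X = rng.standard_normal((10, 2))
        fit = fit_local_model(nbrs, X, LocalModelConfig(algorithm="RF", seed=0))
        assert fit.algorithm_used == "WA"
        assert fit.warnings
        assert weighted_average(nbrs) == pytest.approx(4.2)

    def test_too_few_neighbors_fall_back_to_wa(self, rng):
        nbrs, X = self._neighbors(3, rng, noise=0.1)
        fit = fit_local_model(nbrs, X, LocalModelConfig(algorithm="PLS", seed=0))
        assert fit.algorithm_used == "WA"
        assert "falling back" in fit.warnings[0]

    def test_pls_recovers_noise_free_linear_function(self, rng):
        nbrs, X = self._neighbors(40, rng, noise=0.0)
        fit = fit_local_model(nbrs, X, LocalModelConfig(algorithm="PLS", seed=0),
                              rng=np.random.default_rng(1))
        assert fit.algorithm_used == "PLS"
        q = np.array([0.3, -0.8])
        assert fit.predictor(q) == pytest.approx(0.6, abs=1e-6)
        assert fit.resampling_rmse == pytest.approx(0.0, abs=1e-6)

    def test_rf_approaches_linear_function_inside_range(self, rng):
        nbrs, X = self._neighbors(60, rng, noise=0.01)
        fit = fit_local_model(nbrs, X, LocalModelConfig(algorithm="RF", seed=0),
                              rng=np.random.default_rng(1))
        assert fit.algorithm_used == "RF"
        q = np.array([0.5, 0.0])
        assert fit.predictor(q) == pytest.approx(1.0, abs=0.6)

    def test_wa_never_tunes(self, rng):
        nbrs, X = self._neighbors(20, rng)
        fit = fit_local_model(nbrs, X, LocalModelConfig(algorithm="WA"))
        assert fit.algorithm_used == "WA"
        assert fit.resampling_rmse is None and fit.tuned_hyperparameter is None


class TestPredictOrchestration:
    def _linear_bundle(self, algorithm, rng, n=40, seed=0):
        X = rng.standard_normal((n, 2)) * 0.2 + np.array([1.0, 0.0])
        y = 2.0 * X[:, 0]
        vectors = {f"n{i}": (float(X[i, 0]), float(X[i, 1])) for i in range(n)}
        return quant_bundle(vectors, y.tolist(), algorithm=algorithm, seed=seed)

    def test_out_of_domain_query_gets_warning_no_value(self, rng):
        bundle = self._linear_bundle("WA", rng)
        rec = predict(bundle, query(-1.0, 0.0))  # opposite direction: sim < 0
        assert rec.value is None
        assert rec.neighbors == []
        assert any("applicability domain" in w for w in rec.warnings)

    def test_query_without_relevant_features_is_out_of_domain(self, rng):
        bundle = self._linear_bundle("WA", rng)
        rec = predict(bundle, Substance(id="Q", properties={}))
        assert rec.value is None and rec.warnings

    @pytest.mark.parametrize("algorithm", ["WA", "PLS", "RF"])
    def test_duplicate_of_training_particle_predicted_from_the_rest(self, algorithm, rng):
        bundle = self._linear_bundle(algorithm, rng, seed=3)
        dup = bundle.training.substances[0]
        q = Substance(id="QDUP", properties=dict(dup.properties))
        rec = predict(bundle, q, rng=np.random.default_rng(5))
        assert rec.value is not None
        assert dup.id not in {i for i, _ in rec.neighbors}

    def test_single_neighbor_reduces_to_its_activity_for_all_algorithms(self):
        for algorithm in ["WA", "PLS", "RF"]:
            bundle = quant_bundle({"only": (0.9, np.sqrt(1 - 0.81))}, [7.3],
                                  algorithm=algorithm, threshold=0.5)
            rec = predict(bundle, query(1.0, 0.0))
            assert rec.value == pytest.approx(7.3)
            assert rec.algorithm_used == "WA"

    def test_rf_numerical_failure_falls_back_to_wa(self, rng, monkeypatch):
        bundle = self._linear_bundle("RF", rng)

        def boom(self, X, y, w):
            raise FloatingPointError("synthetic failure")

        monkeypatch.setattr(lm._WeightedRF, "fit", boom)
        rec = predict(bundle, query(1.0, 0.05), rng=np.random.default_rng(2))
        assert rec.algorithm_used == "WA"
        assert rec.value is not None
        assert any("falling back" in w for w in rec.warnings)

    def test_interval_halfwidth_is_196_times_rmse(self, rng):
        bundle = self._linear_bundle("RF", rng)
        rec = predict(bundle, query(1.0, 0.05), rng=np.random.default_rng(2))
        assert rec.algorithm_used == "RF"
        assert rec.interval_high - rec.interval_low > 0
        assert rec.interval_high - rec.value == pytest.approx(rec.value - rec.interval_low)

    def test_predictions_invariant_to_training_order(self, rng):
        bundle = self._linear_bundle("RF", rng, seed=9)
        ds = bundle.training
        perm_ds = Dataset(list(reversed(ds.substances)), ds.feature_names,
                          ds.endpoint_names, ds.descriptor_class, ds.feature_classes)
        bundle2 = build_model(perm_ds, ENDPOINT, "P-CHEM", "RF", relevant=bundle.relevant,
                              model_config=LocalModelConfig(algorithm="RF", seed=9))
        q = query(1.0, 0.1)
        r1 = predict(bundle, q, rng=np.random.default_rng(4))
        r2 = predict(bundle2, q, rng=np.random.default_rng(4))
        assert r1.value == pytest.approx(r2.value, abs=1e-12)
        assert r1.neighbors == r2.neighbors
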