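"""Neighbor search, similarity-weighted local regression and prediction intervals.

The read-across workflow for a query nanoparticle is:

1. find *neighbors* — training particles whose similarity to the query exceeds
   the representation's threshold, excluding any particle identical to the
   query (so duplicates in the data cannot leak the answer);
2. fit a local model on those neighbors only, weighting each neighbor's
   contribution by its similarity to the query;
3. predict, and attach a 95% prediction interval of half-width
   ``1.96 * RMSE`` where the RMSE is the out-of-bootstrap error of the tuned
   local model.

Three local algorithms are supported: the similarity-weighted average (WA, a
fast benchmark with no interval — it has no internal validation), weighted
partial least squares (PLS) and weighted random forests (RF).  PLS/RF tune
their single hyperparameter (number of components / variables per split) by
bootstrap resampling and fall back to WA, with a warning, whenever a
multivariate fit is not meaningful (too few neighbors, constant activities,
numerical failure).

A query with no neighbors is outside the applicability domain: no value is
returned, only warnings.  Every prediction carries its neighbor list so the
rationale can be inspected (and rejected) by an expert.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor

from .datamodel import Dataset, DescriptorClass, PredictionRecord, Substance
from .feature_selection import RelevantFeatureSet, scale_center, select_relevant_features
from .fingerprints import FingerprintError, composite_fingerprint
from .similarity import SimilarityConfig, tanimoto, weighted_cosine_to_matrix

__all__ = [
    "Neighbor",
    "LocalModelConfig",
    "LocalFit",
    "ModelBundle",
    "build_model",
    "find_neighbors",
    "weighted_average",
    "fit_local_model",
    "prediction_interval",
    "predict",
]

log = logging.getLogger(__name__)

ALGORITHMS = ("WA", "PLS", "RF")


@dataclass
class Neighbor:
    """A training substance above the similarity threshold, with its activity."""

    substance_id: str
    similarity: float
    activity: float


@dataclass
class LocalModelConfig:
    """Configuration of the local regression stage.

    ``min_neighbors`` below which PLS/RF defer to WA defaults to 5 — a
    multivariate fit on fewer rows is not meaningful.  ``bootstrap_reps``
    controls hyperparameter tuning and the RMSE estimate feeding the
    prediction interval.  ``seed`` makes per-prediction resampling
    reproducible; when None, entropy seeding is used.
    """

    algorithm: str = "RF"
    min_neighbors: int | None = None  # default: 1 for WA, 5 for PLS/RF
    bootstrap_reps: int = 25
    pi_z: float = 1.96
    rf_trees: int = 50
    max_pls_components: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.min_neighbors is None:
            self.min_neighbors = 1 if self.algorithm == "WA" else 5
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be >= 1")
        if self.bootstrap_reps < 2:
            raise ValueError("bootstrap_reps must be >= 2")


@dataclass
class LocalFit:
    """Result of fitting (or falling back) on one neighbor set."""

    algorithm_used: str
    neighbors: list[Neighbor]
    tuned_hyperparameter: int | None = None
    resampling_rmse: float | None = None
    predictor: Callable[[np.ndarray], float] | None = None  # None for WA
    warnings: list[str] = field(default_factory=list)


@dataclass
class ModelBundle:
    """Everything needed to predict: training data, representation, configs."""

    training: Dataset
    endpoint: str
    descriptor_class: str
    similarity: SimilarityConfig
    model: LocalModelConfig
    relevant: RelevantFeatureSet | None = None  # quantitative classes
    fingerprints: dict[str, frozenset] = field(default_factory=dict)  # MP2D
    scaled: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def build_model(
    training: Dataset,
    endpoint: str,
    descriptor_class: str,
    algorithm: str = "RF",
    alpha: float = 0.05,
    sim_threshold: float | None = None,
    model_config: LocalModelConfig | None = None,
    relevant: RelevantFeatureSet | None = None,
) -> ModelBundle:
    """Assemble a model bundle for one endpoint and descriptor class.

    For quantitative classes this runs endpoint-specific feature selection on
    the training data (unless a precomputed ``relevant`` set is supplied, as
    the crossvalidation driver does) and caches scaled feature vectors.  For
    the fingerprint class it computes composite fingerprints; substances
    without any parseable structure are excluded with a warning.
    """
    if descriptor_class not in DescriptorClass.ALL:
        raise ValueError(f"unknown descriptor class {descriptor_class!r}")
    cfg = model_config or LocalModelConfig(algorithm=algorithm)
    if cfg.algorithm != algorithm:
        cfg = LocalModelConfig(
            algorithm=algorithm,
            bootstrap_reps=cfg.bootstrap_reps,
            pi_z=cfg.pi_z,
            rf_trees=cfg.rf_trees,
            max_pls_components=cfg.max_pls_components,
            seed=cfg.seed,
        )

    if descriptor_class == DescriptorClass.MP2D:
        simcfg = SimilarityConfig(kind="binary", threshold=sim_threshold)
        fps: dict[str, frozenset] = {}
        for s in training.substances:
            try:
                fps[s.id] = composite_fingerprint(s.core_smiles, s.coating_smiles)
            except FingerprintError as exc:
                log.warning("substance %s excluded from fingerprint model: %s", s.id, exc)
        return ModelBundle(
            training=training,
            endpoint=endpoint,
            descriptor_class=descriptor_class,
            similarity=simcfg,
            model=cfg,
            fingerprints=fps,
        )

    features = training.features_for_class(descriptor_class)
    if relevant is None:
        relevant = select_relevant_features(training, endpoint, alpha=alpha, features=features)
    simcfg = SimilarityConfig(
        kind="quantitative", threshold=sim_threshold, weights=relevant.weights or {"_": 1.0}
    )
    scaled = {
        s.id: np.array(
            [
                (s.properties[f.feature] - f.mean) / f.sd if f.feature in s.properties else np.nan
                for f in relevant.stats
            ]
        )
        for s in training.substances
    }
    return ModelBundle(
        training=training,
        endpoint=endpoint,
        descriptor_class=descriptor_class,
        similarity=simcfg,
        model=cfg,
        relevant=relevant,
        scaled=scaled,
    )


def _query_scaled(query: Substance, bundle: ModelBundle) -> np.ndarray:
    assert bundle.relevant is not None
    vals = scale_center(query.properties, bundle.relevant)
    return np.array(
        [vals.get(f, np.nan) for f in bundle.relevant.features], dtype=float
    )


def find_neighbors(query: Substance, bundle: ModelBundle) -> list[Neighbor]:
    """Training substances more similar to the query than the threshold.

    Substances identical to the query — same id, or identical representation
    (equal fingerprint / equal relevant-feature vector) — are eliminated so
    that duplicated particles cannot predict themselves.  Result is sorted by
    descending similarity, ties broken by substance id for determinism.  An
    empty list is a valid outcome and signals the applicability-domain limit.
    """
    endpoint = bundle.endpoint
    thr = bundle.similarity.threshold
    out: list[Neighbor] = []

    if bundle.descriptor_class == DescriptorClass.MP2D:
        try:
            qfp = composite_fingerprint(query.core_smiles, query.coating_smiles)
        except FingerprintError:
            return []
        for s in bundle.training.substances:
            if s.id == query.id or endpoint not in s.endpoints:
                continue
            fp = bundle.fingerprints.get(s.id)
            if fp is None or fp == qfp:
                continue
            sim = tanimoto(qfp, fp)
            if sim > thr:
                out.append(Neighbor(s.id, sim, s.endpoints[endpoint]))
    else:
        q = _query_scaled(query, bundle)
        candidates = [
            s
            for s in bundle.training.substances
            if s.id != query.id and endpoint in s.endpoints
        ]
        if not candidates or np.all(np.isnan(q)):
            return []
        X = np.vstack([bundle.scaled[s.id] for s in candidates])
        w = np.array([abs(f.r) for f in bundle.relevant.stats])
        sims = weighted_cosine_to_matrix(q, X, w)
        for s, sim, row in zip(candidates, sims, X):
            if np.isnan(sim):
                continue
            # identical descriptor vector (same missing pattern, values equal to
            # numerical precision): a duplicate particle, eliminated
            if np.array_equal(np.isnan(row), np.isnan(q)) and np.allclose(
                np.nan_to_num(row), np.nan_to_num(q), rtol=1e-9, atol=1e-12
            ):
                continue
            if sim > thr:
                out.append(Neighbor(s.id, float(sim), s.endpoints[endpoint]))

    out.sort(key=lambda n: (-n.similarity, n.substance_id))
    return out


def weighted_average(neighbors: Sequence[Neighbor]) -> float:
    """Similarity-weighted mean of neighbor activities: Σ sim·y / Σ sim."""
    if not neighbors:
        raise ValueError("weighted average requires at least one neighbor")
    sims = np.array([n.similarity for n in neighbors])
    acts = np.array([n.activity for n in neighbors])
    return float(np.sum(sims * acts) / np.sum(sims))


def prediction_interval(resampling_rmse: float, z: float = 1.96) -> float:
    """Half-width of the 95% prediction interval: ``z * RMSE``."""
    if resampling_rmse < 0:
        raise ValueError("RMSE must be nonnegative")
    return z * resampling_rmse


class _WeightedPLS:
    """PLS regression with per-sample weights via the row-scaling reduction.

    Rows are centered at the weighted means and scaled by sqrt(weight) before
    fitting; the fitted coefficient map is then applied to the raw centered
    query, as in weighted least squares.
    """

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> "_WeightedPLS":
        wn = w / w.sum()
        self.xmean_ = wn @ X
        self.ymean_ = float(wn @ y)
        sw = np.sqrt(w)[:, None]
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit((X - self.xmean_) * sw, (y - self.ymean_) * sw.ravel())
        self.coef_ = np.asarray(pls.coef_).reshape(-1)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ymean_ + (X - self.xmean_) @ self.coef_


class _WeightedRF:
    """Random forest with similarity sample weights and tunable mtry.

    Each tree is grown on a bootstrap resample, so the forest's out-of-bag
    predictions are themselves bootstrapped model predictions; their RMSE is
    the resampled error used for tuning and the prediction interval.
    """

    def __init__(self, max_features: int, n_trees: int, seed: int):
        self.rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=seed,
            bootstrap=True,
            oob_score=True,
            n_jobs=1,
        )

    def fit(self, X: np.ndarray, y: np.ndarray, w: np.ndarray) -> "_WeightedRF":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # few-neighbor OOB coverage warnings
            self.rf.fit(X, y, sample_weight=w)
        oob = self.rf.oob_prediction_
        ok = np.isfinite(oob)
        self.oob_rmse_ = (
            float(np.sqrt(np.mean((oob[ok] - y[ok]) ** 2))) if ok.any() else np.nan
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.rf.predict(X)


def _candidate_grid(algorithm: str, n: int, p: int, cfg: LocalModelConfig) -> list[int]:
    if algorithm == "PLS":
        top = min(cfg.max_pls_components, p, n - 2)
        return list(range(1, max(top, 1) + 1))
    # RF variables-per-split grid: low / middle / all, like common tuning defaults
    if p <= 2:
        return [p]
    return sorted({2, (p + 2) // 2, p})


def fit_local_model(
    neighbors: Sequence[Neighbor],
    X: np.ndarray,
    config: LocalModelConfig,
    rng: np.random.Generator | None = None,
) -> LocalFit:
    """Fit the configured algorithm on a neighbor set, tuning by bootstrap.

    ``X`` is the design matrix over the representation used for similarity
    (0/1 fingerprint bits, or scaled relevant features with missing cells
    already imputed at the training mean).  Rows align with ``neighbors``;
    per-sample weights are the similarities.  Candidate hyperparameters are
    compared by out-of-bootstrap RMSE — for PLS over ``bootstrap_reps``
    explicit resamples shared across candidates, for RF via the forest's
    out-of-bag predictions (each tree already grows on a bootstrap resample).
    The winner's resampled RMSE feeds the prediction interval.

    Any condition that makes a multivariate fit meaningless or fail resolves
    to a WA fallback with a warning, never an exception.
    """
    neighbors = list(neighbors)
    if not neighbors:
        raise ValueError("cannot fit a local model without neighbors")
    fit = LocalFit(algorithm_used="WA", neighbors=neighbors)
    if config.algorithm == "WA":
        return fit

    y = np.array([n.activity for n in neighbors])
    w = np.array([n.similarity for n in neighbors])
    n, p = X.shape if X.ndim == 2 else (len(y), 0)
    if n < config.min_neighbors:
        fit.warnings.append(
            f"{config.algorithm} needs >= {config.min_neighbors} neighbors, got {n}; "
            "falling back to weighted average"
        )
        return fit
    if np.ptp(y) == 0:
        fit.warnings.append(
            "constant neighbor activities; falling back to weighted average"
        )
        return fit
    if p == 0:
        fit.warnings.append("empty descriptor matrix; falling back to weighted average")
        return fit

    rng = rng or np.random.default_rng(config.seed)
    candidates = _candidate_grid(config.algorithm, n, p, config)

    try:
        if config.algorithm == "RF":
            # trees are grown on bootstrap resamples already: tune mtry by
            # out-of-bag RMSE, one forest per candidate
            best_rf: tuple[float, int, _WeightedRF] | None = None
            for cand in candidates:
                model = _WeightedRF(cand, config.rf_trees, int(rng.integers(2**31)))
                model.fit(X, y, w)
                if np.isfinite(model.oob_rmse_) and (
                    best_rf is None or model.oob_rmse_ < best_rf[0]
                ):
                    best_rf = (model.oob_rmse_, cand, model)
            if best_rf is None:
                raise FloatingPointError("no candidate produced a finite OOB RMSE")
            best, final = best_rf[:2], best_rf[2]
        else:
            # explicit bootstrap resamples, shared across candidates
            resamples = []
            for _ in range(config.bootstrap_reps):
                idx = rng.integers(0, n, n)
                oob = np.setdiff1d(np.arange(n), idx)
                if oob.size and np.ptp(y[idx]) > 0:
                    resamples.append((idx, oob))
            if not resamples:
                fit.warnings.append(
                    "bootstrap resampling degenerate; falling back to weighted average"
                )
                return fit
            best = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # PLS constant-residual chatter
                for cand in candidates:
                    sq: list[float] = []
                    for idx, oob in resamples:
                        model = _WeightedPLS(cand).fit(X[idx], y[idx], w[idx])
                        sq.extend((model.predict(X[oob]) - y[oob]) ** 2)
                    rmse = float(np.sqrt(np.mean(sq)))
                    if np.isfinite(rmse) and (best is None or rmse < best[0]):
                        best = (rmse, cand)
                if best is None:
                    raise FloatingPointError("no candidate produced a finite resampled RMSE")
                final = _WeightedPLS(best[1]).fit(X, y, w)

        fit.algorithm_used = config.algorithm
        fit.tuned_hyperparameter = int(best[1])
        fit.resampling_rmse = float(best[0])
        fit.predictor = lambda q: float(final.predict(np.atleast_2d(q))[0])
    except Exception as exc:  # numerical failure of any kind -> WA
        fit.algorithm_used = "WA"
        fit.tuned_hyperparameter = None
        fit.resampling_rmse = None
        fit.predictor = None
        fit.warnings.append(
            f"{config.algorithm} fit failed ({exc}); falling back to weighted average"
        )
    return fit


def _design_matrix(
    query: Substance, neighbors: Sequence[Neighbor], bundle: ModelBundle
) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor design matrix and query vector in the model representation."""
    if bundle.descriptor_class == DescriptorClass.MP2D:
        qfp = composite_fingerprint(query.core_smiles, query.coating_smiles)
        nfps = [bundle.fingerprints[n.substance_id] for n in neighbors]
        bits = sorted(set().union(qfp, *nfps))
        X = np.array([[1.0 if b in fp else 0.0 for b in bits] for fp in nfps])
        q = np.array([1.0 if b in qfp else 0.0 for b in bits])
        return X, q
    X = np.vstack([bundle.scaled[n.substance_id] for n in neighbors])
    q = _query_scaled(query, bundle)
    # scaled space: the training mean is 0, used to fill unmeasured cells for
    # the regression fit only (similarity already accounted for missingness)
    return np.nan_to_num(X, nan=0.0), np.nan_to_num(q, nan=0.0)


def predict(
    bundle: ModelBundle, query: Substance, rng: np.random.Generator | None = None
) -> PredictionRecord:
    """Full read-across prediction for one query substance.

    Orchestrates neighbor search, local model fitting (with WA fallback) and
    the prediction interval.  Queries without the required representation or
    without neighbors yield a record with no value and explanatory warnings —
    they are outside the applicability domain.
    """
    warnings: list[str] = []
    if bundle.descriptor_class == DescriptorClass.MP2D:
        try:
            composite_fingerprint(query.core_smiles, query.coating_smiles)
        except FingerprintError as exc:
            return PredictionRecord(
                query_id=query.id,
                endpoint=bundle.endpoint,
                warnings=[f"no structural representation: {exc}"],
            )
    else:
        measured = [f for f in bundle.relevant.features if f in query.properties]
        if len(bundle.relevant) == 0:
            return PredictionRecord(
                query_id=query.id,
                endpoint=bundle.endpoint,
                warnings=["no relevant features for this endpoint"],
            )
        if len(measured) < 2:
            return PredictionRecord(
                query_id=query.id,
                endpoint=bundle.endpoint,
                warnings=[
                    "outside applicability domain: similarities cannot be determined "
                    f"({len(measured)} of {len(bundle.relevant)} relevant features measured)"
                ],
            )

    neighbors = find_neighbors(query, bundle)
    if not neighbors:
        return PredictionRecord(
            query_id=query.id,
            endpoint=bundle.endpoint,
            warnings=["outside applicability domain: no neighbors above threshold"],
        )

    X, q = _design_matrix(query, neighbors, bundle)
    fit = fit_local_model(neighbors, X, bundle.model, rng=rng)
    warnings.extend(fit.warnings)

    if fit.algorithm_used == "WA":
        value = weighted_average(neighbors)
        lo = hi = None
    else:
        value = fit.predictor(q)
        half = prediction_interval(fit.resampling_rmse, bundle.model.pi_z)
        lo, hi = value - half, value + half

    return PredictionRecord(
        query_id=query.id,
        endpoint=bundle.endpoint,
        value=value,
        interval_low=lo,
        interval_high=hi,
        neighbors=[(n.substance_id, n.similarity) for n in neighbors],
        algorithm_used=fit.algorithm_used,
        warnings=warnings,
    )
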