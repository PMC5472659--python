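"""Endpoint-specific feature filtering and the scaling statistics it freezes.

Measured nanoparticle descriptors are mostly irrelevant for any particular
endpoint; using all of them drowns the informative ones when computing
similarities.  We therefore keep only *relevant* features — those whose
Pearson correlation with the endpoint over the training substances is
significant at ``p < alpha`` (default 0.05, plain filter, no multiple-testing
correction; a deliberately liberal choice, see the methods note).  Filter
selection is preferred over wrapper methods (forward selection, backward
elimination) for its lower overfitting risk.

Missing measurements are handled pairwise-complete per feature.  The training
mean and standard deviation of each retained feature are frozen into the
:class:`RelevantFeatureSet` so that scaling of later queries (and of test
folds during crossvalidation) uses training information only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import stats as sstats

from .datamodel import Dataset

__all__ = [
    "FeatureStats",
    "RelevantFeatureSet",
    "pearson_stats",
    "select_relevant_features",
    "scale_center",
]


@dataclass
class FeatureStats:
    """Per-feature training statistics: correlation with the endpoint and scaling."""

    feature: str
    r: float
    p: float
    n: int
    mean: float
    sd: float


@dataclass
class RelevantFeatureSet:
    """The endpoint-specific selected features with their frozen training stats."""

    endpoint: str
    alpha: float
    stats: list[FeatureStats] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)  # constant / too-sparse features

    @property
    def features(self) -> list[str]:
        return [s.feature for s in self.stats]

    @property
    def weights(self) -> dict[str, float]:
        """Similarity weights: absolute Pearson correlation per feature."""
        return {s.feature: abs(s.r) for s in self.stats}

    def __len__(self) -> int:
        return len(self.stats)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "endpoint": self.endpoint,
            "alpha": self.alpha,
            "stats": [vars(s) for s in self.stats],
            "dropped": self.dropped,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RelevantFeatureSet":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            endpoint=d["endpoint"],
            alpha=d["alpha"],
            stats=[FeatureStats(**s) for s in d["stats"]],
            dropped=list(d["dropped"]),
        )


def pearson_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p-value (t distribution, n-2 df) for complete pairs.

    Raises ``ValueError`` for fewer than 3 pairs or a constant vector; callers
    exclude such features with a warning rather than crash.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sstats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def select_relevant_features(
    dataset: Dataset,
    endpoint: str,
    alpha: float = 0.05,
    features: list[str] | None = None,
) -> RelevantFeatureSet:
    """Retain features correlated with the endpoint at ``p < alpha``.

    Statistics are computed pairwise-complete: for each feature, only
    substances with both the feature and the endpoint measured contribute,
    and the frozen scaling mean/sd come from that same subset.  Features with
    fewer than 3 complete pairs or zero variance are dropped and listed in
    ``RelevantFeatureSet.dropped``.  An empty result is valid — downstream it
    means every query is outside the applicability domain for this endpoint.

    Selection is a pure function of (training substances, endpoint, alpha).
    """
    features = features if features is not None else list(dataset.feature_names)
    y = dataset.endpoint_series(endpoint).to_numpy()
    if np.sum(~np.isnan(y)) < 3:
        raise ValueError(f"endpoint {endpoint!r} has fewer than 3 measured substances")
    X = dataset.feature_frame(features).to_numpy()  # (n, p), NaN = missing

    mask = ~np.isnan(X) & ~np.isnan(y)[:, None]
    n_f = mask.sum(axis=0).astype(float)
    Xz = np.where(mask, X, 0.0)
    Yz = np.where(mask, y[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        mx = Xz.sum(0) / n_f
        my = Yz.sum(0) / n_f
        sxx = (Xz**2).sum(0) - n_f * mx**2
        syy = (Yz**2).sum(0) - n_f * my**2
        sxy = (Xz * Yz).sum(0) - n_f * mx * my
        r = sxy / np.sqrt(sxx * syy)
        # guard rounding just past +/-1 before the t transform
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n_f - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
        p = 2.0 * sstats.t.sf(np.abs(t), n_f - 2)
        sd = np.sqrt(np.maximum(sxx, 0.0) / np.maximum(n_f - 1.0, 1.0))

    stats_list: list[FeatureStats] = []
    dropped: list[str] = []
    for j, f in enumerate(features):
        if n_f[j] < 3 or sxx[j] <= 0 or syy[j] <= 0:
            dropped.append(f)
            continue
        if p[j] < alpha:
            stats_list.append(
                FeatureStats(
                    feature=f,
                    r=float(r[j]),
                    p=float(p[j]),
                    n=int(n_f[j]),
                    mean=float(mx[j]),
                    sd=float(sd[j]),
                )
            )
    return RelevantFeatureSet(endpoint=endpoint, alpha=alpha, stats=stats_list, dropped=dropped)


def scale_center(
    values: Mapping[str, float], stats: RelevantFeatureSet
) -> dict[str, float]:
    """Scale and center a substance's measured values with frozen training stats.

    Only retained features present in ``values`` are returned:
    ``(value - mean) / sd``.  Missing stays missing — imputation is never done
    here; too little overlap between two substances makes them incomparable at
    the similarity stage instead.
    """
    out = {}
    for s in stats.stats:
        if s.feature in values:
            if s.sd <= 0:
                raise ValueError(f"retained feature {s.feature!r} has sd <= 0")
            out[s.feature] = (values[s.feature] - s.mean) / s.sd
    return out


def scaled_matrix(dataset: Dataset, stats: RelevantFeatureSet) -> np.ndarray:
    """Scaled/centered matrix (n x p) over the retained features; NaN = missing."""
    feats = stats.features
    X = dataset.feature_frame(feats).to_numpy()
    mean = np.array([s.mean for s in stats.stats])
    sd = np.array([s.sd for s in stats.stats])
    return (X - mean) / sd
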