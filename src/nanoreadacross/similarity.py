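"""Similarity measures for neighbor identification.

Two measures, one per representation:

* **Binary** (structural fingerprints): the Tanimoto/Jaccard index
  ``|A∩B| / |A∪B|`` with a neighbor threshold of 0.1.
* **Quantitative** (measured properties): weighted cosine similarity of the
  scaled and centered relevant-feature vectors, where each feature's
  contribution is weighted by the magnitude of its Pearson correlation with
  the endpoint, with a neighbor threshold of 0.5.

Absolute correlations ``|r|`` are used as weights so the weighted norms stay
real and nonnegative; the measure is invariant to a global positive rescaling
of the weight vector.  Only features measured on *both* substances enter the
weighted cosine; when fewer than two overlap, or a restricted vector has zero
norm, the pair is incomparable (``NaN``) and feeds the applicability domain
rather than a model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import AbstractSet, Mapping

import numpy as np

__all__ = [
    "SimilarityConfig",
    "tanimoto",
    "weighted_cosine",
    "weighted_cosine_to_matrix",
    "MIN_OVERLAP",
]

#: minimum number of features measured on both substances for a defined similarity
MIN_OVERLAP = 2

#: neighbor thresholds per representation
DEFAULT_THRESHOLDS = {"binary": 0.1, "quantitative": 0.5}


@dataclass
class SimilarityConfig:
    """How to compare two substances: representation kind, threshold, weights."""

    kind: str = "quantitative"  # "binary" | "quantitative"
    threshold: float | None = None
    weights: dict[str, float] = field(default_factory=dict)  # quantitative only

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_THRESHOLDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS[self.kind]
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.weights:
            w = np.array(list(self.weights.values()))
            if (w < 0).any() or not (w > 0).any():
                raise ValueError("weights must be >= 0 with at least one > 0")


def tanimoto(a: AbstractSet[str], b: AbstractSet[str]) -> float:
    """Tanimoto/Jaccard index of two binary fingerprints: |a∩b| / |a∪b|."""
    if not a or not b:
        raise ValueError("Tanimoto undefined for an empty fingerprint")
    inter = len(a & b)
    union = len(a) + len(b) - inter
    return inter / union


def weighted_cosine(
    x: Mapping[str, float], y: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Weighted cosine similarity over the features measured on both substances.

    ``Σ w_f x_f y_f / (sqrt(Σ w_f x_f²) · sqrt(Σ w_f y_f²))`` over the
    intersection of features present in ``x``, ``y`` and ``weights``.
    Returns NaN when fewer than :data:`MIN_OVERLAP` features overlap or a
    restricted vector has zero weighted norm: the pair is incomparable.
    """
    common = [f for f in weights if f in x and f in y]
    if len(common) < MIN_OVERLAP:
        return math.nan
    w = np.array([weights[f] for f in common])
    xv = np.array([x[f] for f in common])
    yv = np.array([y[f] for f in common])
    nx = math.sqrt(float(np.sum(w * xv * xv)))
    ny = math.sqrt(float(np.sum(w * yv * yv)))
    if nx == 0.0 or ny == 0.0:
        return math.nan
    return float(np.sum(w * xv * yv)) / (nx * ny)


def weighted_cosine_to_matrix(
    q: np.ndarray, X: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Weighted cosine of a query vector against each row of a matrix.

    ``q`` is (p,), ``X`` is (n, p); NaN marks missing values in both.  Each
    row's similarity is computed over the features measured on both the query
    and that row, mirroring :func:`weighted_cosine`.  Incomparable rows get
    NaN.
    """
    qmask = ~np.isnan(q)
    Xmask = ~np.isnan(X)
    both = Xmask & qmask[None, :]
    q0 = np.where(qmask, q, 0.0)
    X0 = np.where(Xmask, X, 0.0)
    wq = w * q0
    num = (X0 * both) @ wq
    qnorm = np.sqrt(both @ (w * q0 * q0))
    xnorm = np.sqrt(((X0 * X0) * both) @ w)
    overlap = both.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = num / (qnorm * xnorm)
    sim[(overlap < MIN_OVERLAP) | (qnorm == 0.0) | (xnorm == 0.0)] = np.nan
    return sim
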