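"""Relief feature weighting and thresholded selection.

Classic Relief rewards a feature for separating each instance from its
nearest miss (nearest neighbor of the other class) and penalizes it for
separating the instance from its nearest hit (same class):

    W[f] <- W[f] - diff(f, x, hit)/m + diff(f, x, miss)/m,

with diff(f, a, b) = |a_f - b_f| / range_f, so weights land in [-1, 1].
The default is a deterministic full sweep over all instances with one hit
and one miss (the original formulation); ``n_neighbors > 1`` averages over
the k nearest hits/misses (ReliefF-style) and ``m`` enables classic random
sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .feature_assembly import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ReliefParams:
    """m: sampled instances (None = deterministic full sweep); n_neighbors:
    hits/misses averaged per instance (1 = original Relief); seed: used only
    when m is given."""

    m: Optional[int] = None
    n_neighbors: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m is not None and self.m < 1:
            raise ValueError("m must be >= 1")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")


@dataclass
class ReliefWeights:
    """Per-feature relevance weights with the descending-weight ranking."""

    weights: np.ndarray
    ranking: np.ndarray  # feature indices, best first; ties by column index

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)
        if sorted(self.ranking.tolist()) != list(range(len(self.weights))):
            raise ValueError("ranking must be a permutation of feature indices")


def relief_weights(
    X, y, params: ReliefParams | None = None
) -> ReliefWeights:
    """Compute Relief weights for a binary-labeled feature matrix.

    Features are range-normalized; zero-range (constant) features are
    forced to weight 0 and excluded from the distance computation.
    Nearest hits/misses use Euclidean distance over the normalized
    features, ties broken by row index.
    """
    params = params or ReliefParams()
    values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = values.shape
    if len(np.unique(y)) < 2:
        raise ValueError("Relief requires both classes present")
    ranges = values.max(axis=0) - values.min(axis=0)
    active = ranges > 0
    norm = np.zeros_like(values)
    norm[:, active] = (values[:, active] - values[:, active].min(axis=0)) / ranges[
        active
    ]

    dist = squareform(pdist(norm[:, active])) if active.any() else np.zeros((n, n))
    np.fill_diagonal(dist, np.inf)

    if params.m is None:
        sampled = np.arange(n)
    else:
        rng = np.random.default_rng(params.seed)
        sampled = rng.integers(0, n, size=params.m)
    m = len(sampled)

    w = np.zeros(p)
    k = params.n_neighbors
    for i in sampled:
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        other = np.flatnonzero(y != y[i])
        if same.size == 0:
            raise ValueError(f"instance {i} has no same-class neighbor")
        hits = same[np.lexsort((same, dist[i, same]))][:k]
        misses = other[np.lexsort((other, dist[i, other]))][:k]
        hit_diff = np.abs(norm[hits] - norm[i]).mean(axis=0)
        miss_diff = np.abs(norm[misses] - norm[i]).mean(axis=0)
        w += (miss_diff - hit_diff) / m
    w[~active] = 0.0
    ranking = np.lexsort((np.arange(p), -w))
    return ReliefWeights(weights=w, ranking=ranking)


def select_features(
    fm: FeatureMatrix,
    weights: ReliefWeights,
    top_n: Optional[int] = None,
    threshold: Optional[float] = None,
) -> tuple[FeatureMatrix, dict]:
    """Keep the top-n features by weight, or all features with weight >= tau.

    Exactly one selector must be given. Returns the column-subset matrix
    plus a per-block ledger (block name -> surviving-feature count) in the
    matrix's block order.
    """
    if (top_n is None) == (threshold is None):
        raise ValueError("give exactly one of top_n or threshold")
    n_features = len(weights.weights)
    if top_n is not None:
        if not 1 <= top_n <= n_features:
            raise ValueError(f"top_n must be in [1, {n_features}], got {top_n}")
        kept = np.sort(weights.ranking[:top_n])
    else:
        kept = np.flatnonzero(weights.weights >= threshold)
        if kept.size == 0:
            raise ValueError(
                f"threshold {threshold} exceeds the maximum weight "
                f"{weights.weights.max():.6g}; lower tau"
            )
    sub = fm.subset_columns(kept.tolist())
    ledger = {
        name: int(((kept >= lo) & (kept < hi)).sum())
        for name, (lo, hi) in fm.block_spans.items()
    }
    return sub, ledger
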