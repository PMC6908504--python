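"""Fuzzy annotation distances and K-nearest-neighbor score profiles.

The central idea: a query protein is described by how acetylation-enriched
its neighborhood is. For each annotation vocabulary j (GO, Pfam, ...,
subcellular localization) the distance between proteins p and q mixes the
Jaccard dissimilarity of their keyword sets with the Euclidean distance of
their PseAAC vectors,

    Dist_j(p, q) = w1 * (1 - |A_p ∩ A_q| / |A_p ∪ A_q|) + w2 * d_PseAAC(p, q),

and the KNN score at neighborhood size k is the fraction of acetylated
proteins among the k nearest labeled reference proteins. Sweeping k over a
50-point grid of dataset fractions (0.1% .. 14.8%, step 0.3%) yields one
50-dimensional score block per vocabulary; a special ``PAAC`` source uses
the PseAAC Euclidean distance alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .dataio import SOURCES, Corpus, ProteinRecord
from .sequence_features import PseaacParams, encode_pseaac

logger = logging.getLogger(__name__)

#: Pseudo-source selecting the pure PseAAC Euclidean distance.
PAAC_SOURCE = "PAAC"

#: Default block order when all nine distance flavors are used.
ALL_KNN_SOURCES: tuple[str, ...] = (PAAC_SOURCE,) + SOURCES


@dataclass(frozen=True)
class DistanceWeights:
    """Mixing weights of the set term (w1) and PseAAC term (w2)."""

    w1: float = 0.5
    w2: float = 0.5

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or self.w1 + self.w2 <= 0:
            raise ValueError("weights must be non-negative with w1 + w2 > 0")


@dataclass(frozen=True)
class KnnGrid:
    """Ordered neighborhood fractions defining the k sweep.

    The default grid is 0.001, 0.004, ..., 0.148 (step 0.003): 50 points,
    i.e. 0.1% to 14.8% of the reference-set size.
    """

    fractions: tuple = field(
        default_factory=lambda: tuple(
            round(0.001 + 0.003 * i, 10) for i in range(50)
        )
    )

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size == 0:
            raise ValueError("grid must be non-empty")
        if np.any(f <= 0) or np.any(f > 1):
            raise ValueError("fractions must lie in (0, 1]")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fractions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fractions)

    def k_values(self, n_reference: int) -> np.ndarray:
        """k = max(1, round(f * N)) for each fraction (half-up rounding)."""
        f = np.asarray(self.fractions, dtype=float)
        k = np.floor(f * n_reference + 0.5).astype(int)
        return np.maximum(k, 1)


@dataclass
class KnnScoreBlock:
    """One vocabulary's KNN score profile for one query."""

    source: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("KNN scores must lie in [0, 1]")


def jaccard_dissimilarity(a: frozenset, b: frozenset) -> float:
    """1 - |A∩B|/|A∪B|; two empty sets count as maximally dissimilar (1)."""
    if not a and not b:
        logger.debug("both annotation sets empty; set term = 1")
        return 1.0
    union = len(a | b)
    return 1.0 - len(a & b) / union


def pseaac_cache(records, params: PseaacParams | None = None) -> dict:
    """Map record id -> PseAAC vector for the given records."""
    params = params or PseaacParams()
    return {r.id: encode_pseaac(r.sequence, params) for r in records}


def fuzzy_distance(
    p: ProteinRecord,
    q: ProteinRecord,
    source: str,
    weights: DistanceWeights | None = None,
    cache: dict | None = None,
    params: PseaacParams | None = None,
) -> float:
    """The raw fuzzy distance w1*(1 - Jaccard) + w2*d_PseAAC for one pair.

    For the PAAC pseudo-source only the Euclidean term (weighted by w2)
    applies. Symmetric; zero iff the sets and PseAAC vectors both coincide
    (given positive weights).
    """
    weights = weights or DistanceWeights()
    if cache is not None and p.id in cache and q.id in cache:
        vp, vq = cache[p.id], cache[q.id]
    else:
        params = params or PseaacParams()
        vp = encode_pseaac(p.sequence, params)
        vq = encode_pseaac(q.sequence, params)
    euclid = float(np.linalg.norm(vp - vq))
    if source == PAAC_SOURCE:
        return weights.w2 * euclid
    set_term = jaccard_dissimilarity(p.annotation_set(source), q.annotation_set(source))
    return weights.w1 * set_term + weights.w2 * euclid


def _jaccard_matrix(queries, reference, source) -> np.ndarray:
    qsets = [r.annotation_set(source) for r in queries]
    rsets = [r.annotation_set(source) for r in reference]
    out = np.empty((len(qsets), len(rsets)))
    for i, a in enumerate(qsets):
        for j, b in enumerate(rsets):
            out[i, j] = jaccard_dissimilarity(a, b)
    return out


def _euclid_matrix(queries, reference, cache) -> np.ndarray:
    qv = np.vstack([cache[r.id] for r in queries])
    rv = np.vstack([cache[r.id] for r in reference])
    return cdist(qv, rv)


def _scale_rows(e: np.ndarray) -> np.ndarray:
    """Normalize each query row of the Euclidean matrix into [0, 1] so the
    two distance terms are commensurate; monotone per row, so neighbor
    rankings are preserved."""
    row_max = e.max(axis=1, keepdims=True)
    row_max[row_max == 0] = 1.0
    return e / row_max


def _distance_matrix(queries, reference, source, weights, cache) -> np.ndarray:
    if source == PAAC_SOURCE:
        return _euclid_matrix(queries, reference, cache)
    e = _scale_rows(_euclid_matrix(queries, reference, cache))
    j = _jaccard_matrix(queries, reference, source)
    return weights.w1 * j + weights.w2 * e


def _scores_from_distances(
    dist_row: np.ndarray,
    ref_ids: np.ndarray,
    ref_labels: np.ndarray,
    k_values: np.ndarray,
) -> np.ndarray:
    # stable rank: distance first, record id as deterministic tie-break
    order = np.lexsort((ref_ids, dist_row))
    pos_cum = np.cumsum(ref_labels[order])
    return pos_cum[k_values - 1] / k_values


def knn_score_block(
    query: ProteinRecord,
    reference: Corpus,
    source: str,
    grid: KnnGrid | None = None,
    weights: DistanceWeights | None = None,
    exclude_self: bool = True,
    cache: dict | None = None,
    params: PseaacParams | None = None,
) -> KnnScoreBlock:
    """KNN score profile of one query against a labeled reference corpus.

    With ``exclude_self`` the query's own entry in the reference (matched by
    id) is removed before ranking — mandatory in training mode to avoid
    label leakage.
    """
    grid = grid or KnnGrid()
    weights = weights or DistanceWeights()
    refs = [r for r in reference if not (exclude_self and r.id == query.id)]
    if not refs:
        raise ValueError("reference corpus empty after self-exclusion")
    if any(r.label is None for r in refs):
        raise ValueError("all reference records must be labeled")
    if cache is None:
        cache = pseaac_cache(refs + [query], params)
    dist = _distance_matrix([query], refs, source, weights, cache)[0]
    ref_ids = np.array([r.id for r in refs])
    ref_labels = np.array([r.label for r in refs])
    k_values = grid.k_values(len(refs))
    scores = _scores_from_distances(dist, ref_ids, ref_labels, k_values)
    return KnnScoreBlock(source=source, scores=scores)


def knn_feature_matrix(
    corpus,
    sources=None,
    grid: KnnGrid | None = None,
    weights: DistanceWeights | None = None,
    reference: Corpus | None = None,
    exclude_self: bool = True,
    cache: dict | None = None,
    params: PseaacParams | None = None,
) -> tuple[np.ndarray, list]:
    """KNN score blocks for every record, concatenated over sources.

    ``reference`` defaults to the corpus itself (training mode, with
    ``exclude_self=True``); at prediction time pass the stored training
    reference with ``exclude_self=False``. Returns (matrix, column names)
    with columns named ``<source>_knn_<i>``.
    """
    sources = list(sources) if sources is not None else list(SOURCES)
    grid = grid or KnnGrid()
    weights = weights or DistanceWeights()
    queries = list(corpus)
    refs = list(reference) if reference is not None else queries
    if any(r.label is None for r in refs):
        raise ValueError("all reference records must be labeled")
    if exclude_self and len(refs) < 2:
        raise ValueError("reference must hold at least 2 records for self-exclusion")
    if cache is None:
        cache = pseaac_cache({r.id: r for r in refs + queries}.values(), params)
    ref_ids = np.array([r.id for r in refs])
    ref_labels = np.array([r.label for r in refs])
    ref_index = {rid: i for i, rid in enumerate(ref_ids)}

    n_q, n_grid = len(queries), len(grid)
    out = np.empty((n_q, len(sources) * n_grid))
    for s_i, source in enumerate(sources):
        try:
            dmat = _distance_matrix(queries, refs, source, weights, cache)
        except Exception as exc:
            raise type(exc)(f"source {source!r}: {exc}") from exc
        cols = slice(s_i * n_grid, (s_i + 1) * n_grid)
        for q_i, q in enumerate(queries):
            drop = ref_index.get(q.id) if exclude_self else None
            if drop is None:
                ids, labels, row = ref_ids, ref_labels, dmat[q_i]
            else:
                keep = np.ones(len(refs), dtype=bool)
                keep[drop] = False
                if not keep.any():
                    raise ValueError(
                        f"record {q.id!r}: reference empty after self-exclusion"
                    )
                ids, labels, row = ref_ids[keep], ref_labels[keep], dmat[q_i, keep]
            k_values = grid.k_values(len(ids))
            try:
                out[q_i, cols] = _scores_from_distances(row, ids, labels, k_values)
            except Exception as exc:
                raise type(exc)(f"record {q.id!r}: {exc}") from exc
    names = [f"{s}_knn_{i}" for s in sources for i in range(len(grid))]
    return out, names
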