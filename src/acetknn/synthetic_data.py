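"""Synthetic corpora with the statistical structure the predictor assumes.

Every protein gets an i.i.d. sequence over background residue frequencies,
per-source keyword sets drawn from class-dependent pools, and a synthetic
PSI-BLAST-style PSSM. Class signal enters through two knobs:

* ``enrichment`` — the probability that an acetylated protein draws each
  keyword from a positive-enriched half of the vocabulary rather than the
  shared background half (non-acetylated proteins always draw background);
* ``pssm_signal`` — a log-odds shift added to a fixed subset of PSSM
  columns in positives, mimicking class-correlated conservation.

Presets: ``null`` (no signal anywhere — a negative control), ``weak``
(enrichment 0.4, shift 1) and ``strong`` (enrichment 0.8, shift 2, the
default study condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    AMINO_ACIDS,
    SOURCES,
    Corpus,
    ProteinRecord,
    write_annotations,
    write_fasta,
    write_labels,
    write_pssm,
)
from .annotation_knn import DistanceWeights, KnnGrid, knn_feature_matrix
from .sequence_features import PseaacParams

# Approximate vertebrate proteome residue frequencies (sum to 1).
_BACKGROUND_FREQS = np.array([
    0.0777, 0.0157, 0.0530, 0.0656, 0.0405, 0.0691, 0.0227, 0.0591, 0.0595,
    0.0960, 0.0238, 0.0427, 0.0469, 0.0393, 0.0526, 0.0694, 0.0550, 0.0667,
    0.0118, 0.0311,
])
_BACKGROUND_FREQS = _BACKGROUND_FREQS / _BACKGROUND_FREQS.sum()

#: PSSM columns (in PSI-BLAST order) shifted in positives.
_SIGNAL_COLUMNS = np.arange(5)


@dataclass
class SimParams:
    """Generator settings; the defaults reproduce the benchmark geometry
    (725 acetylated / 2175 non-acetylated proteins, sequences of 30-500
    residues) with strong class signal."""

    n_pos: int = 725
    n_neg: int = 2175
    seq_len: tuple = (30, 500)
    vocab_size: int = 200          # per source; half enriched, half background
    annotations_mean: float = 5.0  # Poisson mean keywords per (protein, source)
    enrichment: float = 0.8        # P(positive draws from enriched pool)
    pssm_signal: float = 2.0       # log-odds column shift in positives
    pssm_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if not 0 <= self.enrichment <= 1:
            raise ValueError("enrichment must lie in [0, 1]")
        if self.seq_len[0] < 30:
            raise ValueError("minimum sequence length is 30 (training filter)")
        if self.vocab_size < 2:
            raise ValueError("vocabulary must hold at least 2 keywords")


PRESETS = {
    "null": dict(enrichment=0.0, pssm_signal=0.0),
    "weak": dict(enrichment=0.4, pssm_signal=1.0),
    "strong": dict(enrichment=0.8, pssm_signal=2.0),
}


def preset(name: str, **overrides) -> SimParams:
    """SimParams for a named preset; keyword overrides win."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimParams(**{**PRESETS[name], **overrides})


def _draw_keywords(rng, source, is_pos, params) -> frozenset:
    half = params.vocab_size // 2
    n_kw = rng.poisson(params.annotations_mean)
    kws = set()
    for _ in range(n_kw):
        use_enriched = is_pos and rng.random() < params.enrichment
        pool_lo = 0 if use_enriched else half
        pool_hi = half if use_enriched else params.vocab_size
        kws.add(f"{source}:{rng.integers(pool_lo, pool_hi):05d}")
    return frozenset(kws)


def _draw_pssm(rng, length, is_pos, params) -> np.ndarray:
    mat = rng.normal(0.0, params.pssm_noise_sd, size=(length, 20))
    if is_pos and params.pssm_signal:
        mat[:, _SIGNAL_COLUMNS] += params.pssm_signal
    return np.clip(np.rint(mat), -9, 9).astype(int)


def simulate_corpus(params: SimParams | None = None, out_dir=None) -> Corpus:
    """Generate a labeled corpus; optionally write it in the package's
    on-disk formats (FASTA, annotations TSV, labels TSV, per-protein
    ``<id>.pssm``). Byte-identical for identical params."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    aa = np.array(list(AMINO_ACIDS))
    records = []
    labels = [1] * params.n_pos + [0] * params.n_neg
    width = len(str(params.n_pos + params.n_neg))
    for i, label in enumerate(labels):
        rid = f"{'pos' if label else 'neg'}{i:0{width}d}"
        length = int(rng.integers(params.seq_len[0], params.seq_len[1] + 1))
        seq = "".join(rng.choice(aa, size=length, p=_BACKGROUND_FREQS))
        annotations = {
            src: _draw_keywords(rng, src, label == 1, params) for src in SOURCES
        }
        pssm = _draw_pssm(rng, length, label == 1, params)
        records.append(
            ProteinRecord(
                id=rid, sequence=seq, label=label, annotations=annotations, pssm=pssm
            )
        )
    corpus = Corpus(records=records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(corpus, out_dir / "sequences.fasta")
        write_annotations(corpus, out_dir / "annotations.tsv")
        write_labels(corpus, out_dir / "labels.tsv")
        pssm_dir = out_dir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for rec in corpus:
            write_pssm(rec.sequence, rec.pssm, pssm_dir / f"{rec.id}.pssm")
    return corpus


def corpus_summary(
    corpus: Corpus,
    sources=None,
    grid: KnnGrid | None = None,
    weights: DistanceWeights | None = None,
    params: PseaacParams | None = None,
) -> pd.DataFrame:
    """Per-source, per-grid-point class comparison of KNN scores.

    Columns: source, grid_index, fraction, mean_pos, mean_neg, gap
    (positive-class mean minus negative-class mean). On a null corpus the
    gap hovers near 0; under enrichment the gap is positive and shrinks as
    the neighborhood fraction grows (scores converge toward the positive
    prevalence).
    """
    sources = list(sources) if sources is not None else list(SOURCES)
    grid = grid or KnnGrid()
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    values, _ = knn_feature_matrix(
        corpus, sources=sources, grid=grid, weights=weights,
        exclude_self=True, params=params,
    )
    y = corpus.labels.astype(int)
    rows = []
    n_grid = len(grid)
    for s_i, source in enumerate(sources):
        block = values[:, s_i * n_grid : (s_i + 1) * n_grid]
        mean_pos = block[y == 1].mean(axis=0)
        mean_neg = block[y == 0].mean(axis=0)
        for g_i, frac in enumerate(grid.fractions):
            rows.append(
                {
                    "source": source,
                    "grid_index": g_i,
                    "fraction": frac,
                    "mean_pos": mean_pos[g_i],
                    "mean_neg": mean_neg[g_i],
                    "gap": mean_pos[g_i] - mean_neg[g_i],
                }
            )
    return pd.DataFrame(rows)


def simulate_feature_table(
    n: int = 300,
    n_informative: int = 20,
    n_noise: int = 80,
    effect: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain feature-level benchmark for Relief: balanced binary labels,
    ``n_informative`` standard-normal features whose class means differ by
    ``effect`` SDs, and ``n_noise`` pure-noise features.

    Returns (X, y, informative_mask).
    """
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.normal(size=(n, n_informative + n_noise))
    X[y == 1, :n_informative] += effect
    mask = np.zeros(n_informative + n_noise, dtype=bool)
    mask[:n_informative] = True
    return X, y, mask
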