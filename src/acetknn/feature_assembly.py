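"""Declarative composition of named feature blocks into a model matrix.

A :class:`FeatureConfig` lists ordered blocks drawn from ``pseaac``,
``gray_pssm`` and ``knn:<source>`` (sources: the eight annotation
vocabularies plus ``PAAC``); :func:`assemble` turns a corpus into a
:class:`FeatureMatrix` carrying column names, row ids and block spans.
Optional per-block scalar weights multiply that block's columns —
downstream Relief supplies data-driven importance, so they default to 1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import SOURCES, Corpus
from .sequence_features import (
    PseaacParams,
    encode_gray_pssm,
    gray_pssm_feature_names,
    pseaac_feature_names,
)
from .annotation_knn import (
    ALL_KNN_SOURCES,
    DistanceWeights,
    KnnGrid,
    knn_feature_matrix,
    pseaac_cache,
)

_VALID_KNN = set(ALL_KNN_SOURCES)


@dataclass
class FeatureConfig:
    """Ordered block list plus per-block parameters.

    blocks: names from {"pseaac", "gray_pssm", "knn:<source>"}, unique.
    block_weights: optional scalar multiplier per block (default 1.0).
    missing_pssm: "error" or "zero" — what gray_pssm does for records
    without a profile.
    """

    blocks: tuple = ()
    block_weights: dict = field(default_factory=dict)
    pseaac: PseaacParams = field(default_factory=PseaacParams)
    knn_grid: KnnGrid = field(default_factory=KnnGrid)
    knn_weights: DistanceWeights = field(default_factory=DistanceWeights)
    gray_rescale: str = "logistic"
    missing_pssm: str = "error"

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one feature block is required")
        if len(set(self.blocks)) != len(self.blocks):
            raise ValueError("block names must be unique")
        for b in self.blocks:
            if b in {"pseaac", "gray_pssm"}:
                continue
            if b.startswith("knn:") and b[4:] in _VALID_KNN:
                continue
            raise ValueError(
                f"unknown block {b!r}; expected 'pseaac', 'gray_pssm' or "
                f"'knn:<{'|'.join(ALL_KNN_SOURCES)}>'"
            )
        unknown = set(self.block_weights) - set(self.blocks)
        if unknown:
            raise ValueError(f"block_weights for unknown blocks: {sorted(unknown)}")

    @classmethod
    def default_375(cls) -> "FeatureConfig":
        """Seven FDA KNN blocks + type-1 PseAAC(lambda=5): 375 columns."""
        fda = [s for s in SOURCES if s != "SL"]
        return cls(blocks=tuple(f"knn:{s}" for s in fda) + ("pseaac",))

    @classmethod
    def full_pool(cls) -> "FeatureConfig":
        """Gray-PSSM + PseAAC + all nine KNN blocks: 80+25+450 = 555 columns."""
        return cls(
            blocks=("gray_pssm", "pseaac")
            + tuple(f"knn:{s}" for s in ALL_KNN_SOURCES)
        )

    def knn_sources(self) -> list:
        return [b[4:] for b in self.blocks if b.startswith("knn:")]

    def block_width(self, block: str) -> int:
        if block == "pseaac":
            return self.pseaac.n_features
        if block == "gray_pssm":
            return 80
        return len(self.knn_grid)

    @property
    def n_features(self) -> int:
        return sum(self.block_width(b) for b in self.blocks)

    def to_dict(self) -> dict:
        return {
            "blocks": list(self.blocks),
            "block_weights": dict(self.block_weights),
            "pseaac": {"lam": self.pseaac.lam, "weight": self.pseaac.weight},
            "knn_grid": list(self.knn_grid.fractions),
            "knn_weights": {"w1": self.knn_weights.w1, "w2": self.knn_weights.w2},
            "gray_rescale": self.gray_rescale,
            "missing_pssm": self.missing_pssm,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class FeatureMatrix:
    """n_records x n_features values with full column provenance."""

    values: np.ndarray
    columns: list
    ids: list
    block_spans: dict  # block name -> (start, stop)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.columns)):
            raise ValueError("values shape inconsistent with ids/columns")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def block_of(self, column_index: int) -> str:
        for name, (lo, hi) in self.block_spans.items():
            if lo <= column_index < hi:
                return name
        raise IndexError(column_index)

    def subset_columns(self, indices) -> "FeatureMatrix":
        indices = list(indices)
        # surviving columns keep their block identity; spans stay contiguous
        # because selections preserve the original column order within blocks
        cursor_by_block = {}
        for new_i, old_i in enumerate(indices):
            b = self.block_of(old_i)
            if b not in cursor_by_block:
                cursor_by_block[b] = [new_i, new_i + 1]
            else:
                cursor_by_block[b][1] = new_i + 1
        new_spans = {b: tuple(v) for b, v in cursor_by_block.items()}
        return FeatureMatrix(
            values=self.values[:, indices],
            columns=[self.columns[i] for i in indices],
            ids=list(self.ids),
            block_spans=new_spans,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.columns)

    def save(self, path, config: FeatureConfig | None = None) -> None:
        """TSV matrix + JSON sidecar (block spans, optional config hash)."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="protein_id")
        sidecar = {
            "block_spans": {k: list(v) for k, v in self.block_spans.items()},
        }
        if config is not None:
            sidecar["config_hash"] = config.config_hash()
            sidecar["config"] = config.to_dict()
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            sidecar = json.load(fh)
        return cls(
            values=df.to_numpy(),
            columns=list(df.columns),
            ids=list(df.index),
            block_spans={k: tuple(v) for k, v in sidecar["block_spans"].items()},
        )


def assemble(
    corpus: Corpus,
    config: FeatureConfig,
    reference: Corpus | None = None,
    exclude_self: bool | None = None,
) -> FeatureMatrix:
    """Build the model matrix for ``corpus`` under ``config``.

    ``reference`` is the labeled corpus KNN blocks score against; it
    defaults to ``corpus`` itself with self-exclusion (training mode).
    Passing an explicit reference switches to prediction mode
    (``exclude_self=False``) unless overridden.
    """
    if exclude_self is None:
        exclude_self = reference is None
    records = list(corpus)
    cache_records = {r.id: r for r in records}
    if reference is not None:
        for r in reference:
            cache_records.setdefault(r.id, r)
    cache = pseaac_cache(cache_records.values(), config.pseaac)

    pieces, columns, spans = [], [], {}
    knn_sources = config.knn_sources()
    knn_values = knn_names = None
    if knn_sources:
        knn_values, knn_names = knn_feature_matrix(
            corpus,
            sources=knn_sources,
            grid=config.knn_grid,
            weights=config.knn_weights,
            reference=reference,
            exclude_self=exclude_self,
            cache=cache,
        )
    cursor = 0
    for block in config.blocks:
        if block == "pseaac":
            vals = np.vstack([cache[r.id] for r in records])
            names = pseaac_feature_names(config.pseaac)
        elif block == "gray_pssm":
            rows = []
            for r in records:
                if r.pssm is None:
                    if config.missing_pssm == "zero":
                        rows.append(np.zeros(80))
                        continue
                    raise ValueError(
                        f"record {r.id!r} has no PSSM and missing_pssm='error'"
                    )
                rows.append(encode_gray_pssm(r.pssm, rescale=config.gray_rescale))
            vals = np.vstack(rows) if rows else np.empty((0, 80))
            names = gray_pssm_feature_names()
        else:
            src = block[4:]
            s_i = knn_sources.index(src)
            width = len(config.knn_grid)
            vals = knn_values[:, s_i * width : (s_i + 1) * width]
            names = knn_names[s_i * width : (s_i + 1) * width]
        weight = float(config.block_weights.get(block, 1.0))
        if weight != 1.0:
            vals = vals * weight
        pieces.append(vals)
        columns.extend(names)
        spans[block] = (cursor, cursor + vals.shape[1])
        cursor += vals.shape[1]
    values = np.hstack(pieces)
    return FeatureMatrix(
        values=values, columns=columns, ids=[r.id for r in records], block_spans=spans
    )
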