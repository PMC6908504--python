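"""Model/Results facade over the feature, selection and evaluation layers.

``AcetylationModel`` is built from a labeled :class:`~acetknn.dataio.Corpus`
(or directly from files); ``fit()`` runs per-fold Relief + random-forest
cross-validation, trains the final predictor on all records, and returns an
``AcetylationResults`` carrying the per-fold metrics, their mean and SD,
Relief weights and the trained bundle, with ``summary()``, ``predict()``
and ``plot_roc()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .dataio import Corpus, balanced_datasets, load_corpus, partition_negatives
from .feature_assembly import FeatureConfig
from .model_eval import (
    CvPlan,
    CvResult,
    Predictor,
    RandomForestParams,
    cross_validate,
    train_final,
)
from .relief_selection import ReliefParams


class AcetylationModel:
    """Protein-level acetylation predictor.

    Parameters
    ----------
    corpus : Corpus
        Labeled proteins (1 = acetylated). Balanced corpora are what the
        evaluation protocol assumes; see :func:`evaluate_balanced_datasets`
        for the three-dataset layout built from a large negative pool.
    feature_config : FeatureConfig, optional
        Defaults to the 375-column layout: KNN score blocks for the seven
        functional-domain vocabularies plus type-1 PseAAC(lambda=5).
    top_n : int, optional
        Number of Relief-selected features per fold / for the final model
        (default 156; clipped to the pool size). None disables selection.
    """

    def __init__(
        self,
        corpus: Corpus,
        feature_config: Optional[FeatureConfig] = None,
        relief_params: Optional[ReliefParams] = None,
        rf_params: Optional[RandomForestParams] = None,
        top_n: Optional[int] = 156,
    ) -> None:
        if any(r.label is None for r in corpus):
            raise ValueError("all records must be labeled for fitting")
        self.corpus = corpus
        self.feature_config = feature_config or FeatureConfig.default_375()
        self.relief_params = relief_params or ReliefParams()
        self.rf_params = rf_params or RandomForestParams()
        self.top_n = top_n

    @classmethod
    def from_files(
        cls,
        fasta,
        annotations=None,
        labels=None,
        pssm_dir=None,
        missing_pssm: str = "error",
        **kwargs,
    ) -> "AcetylationModel":
        corpus = load_corpus(
            fasta, annotations, labels, pssm_dir, missing_pssm=missing_pssm
        )
        return cls(corpus, **kwargs)

    def fit(self, seed: int = 0, cv: bool = True, n_folds: int = 5) -> "AcetylationResults":
        cv_result = None
        if cv:
            cv_result = cross_validate(
                self.corpus,
                self.feature_config,
                relief_params=self.relief_params,
                rf_params=self.rf_params,
                plan=CvPlan(n_folds=n_folds, seed=seed),
                top_n=self.top_n,
            )
        predictor = train_final(
            self.corpus,
            self.feature_config,
            relief_params=self.relief_params,
            rf_params=self.rf_params,
            top_n=self.top_n,
            seed=seed,
        )
        return AcetylationResults(model=self, cv=cv_result, predictor=predictor)


@dataclass
class AcetylationResults:
    """Fitted predictor plus cross-validation diagnostics."""

    model: AcetylationModel
    cv: Optional[CvResult]
    predictor: Predictor

    @property
    def relief_weights(self):
        return self.predictor.relief

    @property
    def selected_columns(self) -> list:
        return list(self.predictor.selected_columns)

    def predict(self, records) -> pd.DataFrame:
        return self.predictor.predict(records)

    def summary(self) -> str:
        """Human-readable fit summary (metrics on the 0-1 scale)."""
        lines = []
        n_pos = len(self.model.corpus.positives())
        n_neg = len(self.model.corpus.negatives())
        cfg = self.model.feature_config
        lines.append("Acetylation predictor (KNN annotation scores + PseAAC + RF)")
        lines.append("=" * 62)
        lines.append(f"Records:           {len(self.model.corpus)} "
                     f"({n_pos} acetylated / {n_neg} non-acetylated)")
        lines.append(f"Feature blocks:    {', '.join(cfg.blocks)}")
        lines.append(f"Feature pool:      {cfg.n_features} columns")
        lines.append(f"Selected features: {len(self.selected_columns)}"
                     + ("" if self.model.top_n else " (no selection)"))
        if self.cv is not None:
            lines.append("")
            lines.append(f"{self.cv.to_frame().round(4).to_string()}")
            lines.append("")
            lines.append(f"Pooled AUC: {self.cv.pooled.auc:.4f}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """Plot the pooled cross-validation ROC curve."""
        if self.cv is None or self.cv.pooled.roc is None:
            raise ValueError("no cross-validation ROC available; fit with cv=True")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        roc = self.cv.pooled.roc
        ax.plot(roc[:, 0], roc[:, 1], label=f"AUC = {self.cv.pooled.auc:.3f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend()
        return ax


def evaluate_balanced_datasets(
    corpus: Corpus,
    feature_config: Optional[FeatureConfig] = None,
    relief_params: Optional[ReliefParams] = None,
    rf_params: Optional[RandomForestParams] = None,
    top_n: Optional[int] = 156,
    seed: int = 0,
    n_folds: int = 5,
) -> dict:
    """The three-dataset protocol: split the negative pool into three
    disjoint subsets, cross-validate each balanced dataset, and report
    per-dataset results plus the across-dataset mean of fold means.

    Returns {"datasets": [CvResult x3], "mean": DataFrame}.
    """
    partitioned = partition_negatives(corpus, seed=seed)
    results = []
    for ds in balanced_datasets(partitioned):
        results.append(
            cross_validate(
                ds,
                feature_config or FeatureConfig.default_375(),
                relief_params=relief_params,
                rf_params=rf_params,
                plan=CvPlan(n_folds=n_folds, seed=seed),
                top_n=top_n,
            )
        )
    means = pd.DataFrame([r.mean.as_dict() for r in results],
                         index=[f"dataset{i+1}" for i in range(len(results))])
    means.loc["mean"] = means.mean()
    return {"datasets": results, "mean": means}
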