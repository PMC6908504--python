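"""Random-forest engine, stratified 5-fold cross-validation, and the seven
confusion-matrix metrics plus ROC/AUC.

The evaluation protocol is leakage-free by construction: within each fold
the KNN reference corpus, the Relief weights and the forest are all fitted
on the training records only; test records never contribute neighbors,
labels or feature statistics to anything the model sees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .dataio import Corpus
from .feature_assembly import FeatureConfig, assemble
from .relief_selection import ReliefParams, ReliefWeights, relief_weights, select_features

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Scalar metrics plus the ROC polyline for one evaluation."""

    acc: float
    mcc: float
    sn: float
    sp: float
    pre: float
    f_m: float
    gmean: float
    roc: Optional[np.ndarray] = None  # (n_points, 2) of (fpr, tpr)
    auc: Optional[float] = None

    def as_dict(self) -> dict:
        out = {
            "acc": self.acc, "mcc": self.mcc, "sn": self.sn, "sp": self.sp,
            "pre": self.pre, "f_m": self.f_m, "gmean": self.gmean,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.debug("%s: 0/0 encountered; returning 0 by convention", what)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Closed-form metrics from a confusion matrix; any 0/0 maps to 0."""
    if c.n == 0:
        raise ValueError("no evaluated samples")
    acc = (c.tp + c.tn) / c.n
    sn = _safe_div(c.tp, c.tp + c.fn, "Sn")
    sp = _safe_div(c.tn, c.tn + c.fp, "Sp")
    pre = _safe_div(c.tp, c.tp + c.fp, "Pre")
    f_m = _safe_div(2 * pre * sn, pre + sn, "F-m")
    gmean = float(np.sqrt(sn * sp))
    mcc_den = np.sqrt(
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, "Mcc")
    return MetricsReport(acc=acc, mcc=mcc, sn=sn, sp=sp, pre=pre, f_m=f_m, gmean=gmean)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def roc_auc(scores, y) -> tuple[np.ndarray, float]:
    """ROC polyline (fpr, tpr) and trapezoid AUC from continuous scores.

    The threshold sweep is over unique scores in descending order; with
    ties the result equals the tie-corrected Mann-Whitney statistic.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float))
    points = np.column_stack([fpr, tpr])
    return points, float(_sk_auc(fpr, tpr))


@dataclass
class RandomForestParams:
    """Forest hyperparameters (unremarkable defaults: 500 trees, sqrt(p)
    features per split)."""

    n_estimators: int = 500
    max_features: str | float = "sqrt"
    max_depth: Optional[int] = None
    min_samples_leaf: int = 1

    def build(self, seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            oob_score=False,
            random_state=seed,
            n_jobs=1,
        )


@dataclass
class CvPlan:
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def splitter(self) -> StratifiedKFold:
        if not self.stratified:
            raise NotImplementedError("only stratified folds are supported")
        return StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed
        )


@dataclass
class CvResult:
    """Per-fold metrics, their mean and SD, and the pooled ROC."""

    fold_reports: list
    mean: MetricsReport
    sd: dict
    pooled: MetricsReport
    fold_assignments: dict  # record id -> fold index
    ledgers: list  # per-fold Relief selection ledgers

    def to_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.fold_reports]
        df = pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(len(rows))])
        df.loc["mean"] = pd.Series(self.mean.as_dict())
        df.loc["sd"] = pd.Series(self.sd)
        return df


def _aggregate(reports: list) -> tuple[MetricsReport, dict]:
    frames = pd.DataFrame([r.as_dict() for r in reports])
    mean = frames.mean()
    sd = frames.std(ddof=1) if len(frames) > 1 else frames.mul(0.0).iloc[0]
    mean_report = MetricsReport(**{k: float(mean[k]) for k in
                                   ("acc", "mcc", "sn", "sp", "pre", "f_m", "gmean")})
    mean_report.auc = float(mean["auc"]) if "auc" in mean else None
    sd_dict = {k: float(v) for k, v in sd.items()}
    return mean_report, sd_dict


def cross_validate(
    corpus: Corpus,
    config: FeatureConfig,
    relief_params: ReliefParams | None = None,
    rf_params: RandomForestParams | None = None,
    plan: CvPlan | None = None,
    top_n: Optional[int] = None,
) -> CvResult:
    """Stratified k-fold CV with per-fold KNN references and per-fold Relief.

    ``top_n`` is the number of Relief-selected features per fold (clipped to
    the pool size); None disables selection.
    """
    relief_params = relief_params or ReliefParams()
    rf_params = rf_params or RandomForestParams()
    plan = plan or CvPlan()
    y = corpus.labels.astype(int)
    ids = np.array(corpus.ids)

    fold_reports, ledgers = [], []
    fold_assignments: dict = {}
    pooled_scores, pooled_y = [], []
    for fold_i, (train_idx, test_idx) in enumerate(
        plan.splitter().split(np.zeros(len(y)), y)
    ):
        train = corpus.subset(ids[train_idx])
        test = corpus.subset(ids[test_idx])
        for rid in ids[test_idx]:
            fold_assignments[rid] = fold_i

        X_train = assemble(train, config)  # reference = train, exclude_self
        X_test = assemble(test, config, reference=train, exclude_self=False)
        y_train, y_test = y[train_idx], y[test_idx]

        ledger = None
        if top_n is not None:
            n_keep = min(top_n, X_train.shape[1])
            rw = relief_weights(X_train, y_train, relief_params)
            X_train, ledger = select_features(X_train, rw, top_n=n_keep)
            kept = [fm_col for fm_col in X_train.columns]
            col_idx = [X_test.columns.index(c) for c in kept]
            X_test = X_test.subset_columns(col_idx)
        ledgers.append(ledger)

        rf = rf_params.build(seed=plan.seed + 1000 * fold_i)
        rf.fit(X_train.values, y_train)
        proba = rf.predict_proba(X_test.values)[:, list(rf.classes_).index(1)]
        pred = (proba >= 0.5).astype(int)
        report = compute_metrics(confusion_from_predictions(y_test, pred))
        try:
            report.roc, report.auc = roc_auc(proba, y_test)
        except ValueError:
            report.auc = None
        fold_reports.append(report)
        pooled_scores.append(proba)
        pooled_y.append(y_test)

    mean_report, sd = _aggregate(fold_reports)
    scores_all = np.concatenate(pooled_scores)
    y_all = np.concatenate(pooled_y)
    pooled_pred = (scores_all >= 0.5).astype(int)
    pooled = compute_metrics(confusion_from_predictions(y_all, pooled_pred))
    pooled.roc, pooled.auc = roc_auc(scores_all, y_all)
    return CvResult(
        fold_reports=fold_reports,
        mean=mean_report,
        sd=sd,
        pooled=pooled,
        fold_assignments=fold_assignments,
        ledgers=ledgers,
    )


@dataclass
class Predictor:
    """A trained bundle: forest + Relief-selected columns + the KNN
    reference corpus + the feature-config hash used at training time."""

    rf: RandomForestClassifier
    config: FeatureConfig
    reference: Corpus
    selected_columns: list
    relief: Optional[ReliefWeights] = None
    config_hash: str = ""

    def predict(self, records, config: FeatureConfig | None = None) -> pd.DataFrame:
        """Score new records against the stored training reference.

        Returns a DataFrame (id, probability, call) in input order; the
        binary call thresholds the probability at 0.5. Passing a config
        whose hash differs from the training one is refused.
        """
        if config is not None and config.config_hash() != self.config_hash:
            raise ValueError(
                "feature-config hash mismatch between trained bundle "
                f"({self.config_hash}) and query encoding ({config.config_hash()}); "
                "re-encode queries with the training configuration"
            )
        query = records if isinstance(records, Corpus) else Corpus(list(records))
        for rec in query:
            if all(not rec.annotation_set(s) for s in self.config.knn_sources()
                   if s != "PAAC"):
                logger.warning(
                    "record %s has no annotations in any source; set terms "
                    "default to maximal dissimilarity", rec.id
                )
        fm = assemble(query, self.config, reference=self.reference, exclude_self=False)
        col_idx = [fm.columns.index(c) for c in self.selected_columns]
        X = fm.subset_columns(col_idx).values
        proba = self.rf.predict_proba(X)[:, list(self.rf.classes_).index(1)]
        return pd.DataFrame(
            {
                "protein_id": query.ids,
                "probability": proba,
                "call": (proba >= 0.5).astype(int),
            }
        )


def train_final(
    corpus: Corpus,
    config: FeatureConfig,
    relief_params: ReliefParams | None = None,
    rf_params: RandomForestParams | None = None,
    top_n: Optional[int] = None,
    seed: int = 0,
) -> Predictor:
    """Fit Relief + forest on the full corpus and freeze it with its KNN
    reference for later prediction."""
    rf_params = rf_params or RandomForestParams()
    fm = assemble(corpus, config)
    y = corpus.labels.astype(int)
    rw = None
    if top_n is not None:
        n_keep = min(top_n, fm.shape[1])
        rw = relief_weights(fm, y, relief_params or ReliefParams())
        fm, _ = select_features(fm, rw, top_n=n_keep)
    rf = rf_params.build(seed=seed)
    rf.fit(fm.values, y)
    return Predictor(
        rf=rf,
        config=config,
        reference=corpus,
        selected_columns=list(fm.columns),
        relief=rw,
        config_hash=config.config_hash(),
    )
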