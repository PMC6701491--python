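"""Stratified k-fold cross-validation with leakage-safe over-sampling.

Each iteration over-samples the k-1 training folds with SMOTE, fits a
fresh boosted ensemble, and scores the untouched validation fold.
Synthetic rows therefore never reach a validation fold by construction,
and the union of validation folds is exactly the labelled set.  Reported
per fold: ROC/AUC (Mann-Whitney with midrank ties, identical to the
trapezoidal area under the ROC) and per-class + macro precision /
recall / F1 at a configurable probability threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .classifier import BoosterConfig, TrainedModel, predict_scores, train_classifier
from .config import RunConfig
from .data_io import FeatureTable, LabelSet
from .resample import smote_oversample

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _prf(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def confusion_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """Per-class and macro precision/recall/F1.

    The negative class is scored with the roles of the counts swapped
    (its "true positives" are the TN cell).  Zero denominators yield 0.
    """
    p_pos, r_pos, f_pos = _prf(counts.tp, counts.fp, counts.fn)
    p_neg, r_neg, f_neg = _prf(counts.tn, counts.fn, counts.fp)
    return {
        "precision_pos": p_pos, "recall_pos": r_pos, "f1_pos": f_pos,
        "precision_neg": p_neg, "recall_neg": r_neg, "f1_neg": f_neg,
        "precision_macro": (p_pos + p_neg) / 2,
        "recall_macro": (r_pos + r_neg) / 2,
        "f1_macro": (f_pos + f_neg) / 2,
    }


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> Tuple[float, np.ndarray]:
    """AUC via the Mann-Whitney statistic with midrank tie handling.

    Returns (auc, roc_points) where roc_points is an (m, 2) array of
    (FPR, TPR) starting at (0, 0) and ending at (1, 1); the trapezoidal
    area under those points equals the returned AUC.
    """
    y_true = np.asarray(y_true).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC/AUC needs both classes present")
    ranks = rankdata(scores)  # midranks
    auc = (ranks[y_true].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # ROC points: sweep thresholds over unique scores, descending
    order = np.argsort(-scores, kind="mergesort")
    ys = y_true[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep the last index of each tied score block
    keep = np.r_[np.flatnonzero(np.diff(ss) != 0), len(ss) - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    return float(auc), np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_folds(
    gene_ids: Sequence[str],
    labels: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Fold index (0..n_folds-1) per labelled gene, stratified and shuffled."""
    labels = np.asarray(labels)
    for c in np.unique(labels):
        if (labels == c).sum() < n_folds:
            raise ValueError(
                f"class {c!r} has fewer members than n_folds={n_folds};"
                " reduce the fold count"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[val_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    auc: float
    roc: np.ndarray
    metrics: Dict[str, float]
    counts: ConfusionCounts


@dataclass
class CVReport:
    folds: List[FoldResult]
    config: RunConfig
    mean_auc: float = field(init=False)
    sd_auc: float = field(init=False)
    mean_macro: Dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        aucs = np.array([f.auc for f in self.folds])
        self.mean_auc = float(aucs.mean())
        self.sd_auc = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0
        self.mean_macro = {
            key: float(np.mean([f.metrics[key] for f in self.folds]))
            for key in ("precision_macro", "recall_macro", "f1_macro")
        }

    @property
    def min_auc(self) -> float:
        return min(f.auc for f in self.folds)

    @property
    def max_auc(self) -> float:
        return max(f.auc for f in self.folds)

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": round(self.sd_auc, 3),
            "min_auc": self.min_auc,
            "max_auc": self.max_auc,
            "mean_macro": self.mean_macro,
            "folds": [
                {
                    "fold": f.fold,
                    "auc": f.auc,
                    "metrics": f.metrics,
                    "counts": {"tp": f.counts.tp, "fp": f.counts.fp,
                               "fn": f.counts.fn, "tn": f.counts.tn},
                }
                for f in self.folds
            ],
            "config": self.config.to_dict(),
        }


def labelled_arrays(
    table: FeatureTable, labels: LabelSet
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Extract (X, y, gene_ids) for the labelled genes, table order."""
    ids, ys = [], []
    for g in table.gene_ids:
        if g in labels.positive:
            ids.append(g)
            ys.append(1)
        elif g in labels.negative:
            ids.append(g)
            ys.append(0)
    sub = table.subset_genes(ids)
    return sub.values, np.array(ys), ids


def run_cv(
    table: FeatureTable,
    labels: LabelSet,
    config: Optional[RunConfig] = None,
    single_tree: bool = False,
) -> CVReport:
    """Stratified n-fold CV with SMOTE on training folds only.

    ``single_tree`` swaps the boosted ensemble for one depth-limited
    tree (a 1-estimator, learning-rate-1 booster) — the ablation
    baseline; everything else, folds included, is held fixed.
    """
    config = config or RunConfig()
    X, y, ids = labelled_arrays(table, labels)
    assignment = stratified_folds(ids, y, config.n_folds, config.seed)

    folds: List[FoldResult] = []
    for fold in range(config.n_folds):
        val = assignment == fold
        train = ~val
        Xtr, ytr = X[train], y[train]
        if config.smote:
            rs = smote_oversample(
                Xtr, ytr, k=config.smote_k,
                target_ratio=config.smote_target_ratio,
                rng_seed=np.random.default_rng(config.seed * 100003 + fold),
            )
            Xtr, ytr = rs.values, rs.labels
        bc = config.booster
        fold_cfg = BoosterConfig(
            n_estimators=1 if single_tree else bc.n_estimators,
            max_depth=bc.max_depth,
            learning_rate=1.0 if single_tree else bc.learning_rate,
            colsample_bytree=1.0 if single_tree else bc.colsample_bytree,
            subsample=1.0 if single_tree else bc.subsample,
            gamma=bc.gamma,
            objective=bc.objective,
            n_jobs=bc.n_jobs,
            seed=config.seed + fold,
        )
        model = train_classifier(Xtr, ytr, fold_cfg)
        scores = predict_scores(model, X[val])
        auc, roc = roc_auc(y[val], scores)
        pred = scores > config.decision_threshold
        truth = y[val] == 1
        counts = ConfusionCounts(
            tp=int((pred & truth).sum()),
            fp=int((pred & ~truth).sum()),
            fn=int((~pred & truth).sum()),
            tn=int((~pred & ~truth).sum()),
        )
        folds.append(FoldResult(fold, auc, roc, confusion_metrics(counts), counts))
        logger.info("fold %d: auc=%.3f", fold, auc)
    return CVReport(folds, config)
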