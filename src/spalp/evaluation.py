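"""Confusion-matrix metrics, ROC/PR curves with AUC, and the CV harness.

Scalar metrics use the standard confusion-count formulas; the ROC curve
sweeps every distinct score threshold and its area is integrated by the
trapezoid rule, which coincides with rank concordance (ties counted 1/2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from . import autoencoder, mlp
from .autoencoder import AEConfig
from .dataset import fuse_features, make_sample_set, sample_negatives
from .io_formats import AdjacencyMatrix, AssociationCatalog, SimilarityMatrix
from .mlp import MLPConfig

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
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    tpr: float
    fpr: float
    auc: float | None = None

    def as_dict(self) -> dict[str, float]:
        out = {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tpr": self.tpr,
            "fpr": self.fpr,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def _validate_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be aligned 1-D arrays")
    if labels.size and not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels, scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Counts with prediction = 1 iff score >= threshold (ties positive)."""
    labels, scores = _validate_scores(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator computing {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall, F1, TPR and FPR from confusion counts."""
    if c.total == 0:
        raise ValueError("no evaluated pairs")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        precision=_safe_div(c.tp, c.tp + c.fp, "precision"),
        recall=recall,
        f1=_safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
        tpr=recall,
        fpr=_safe_div(c.fp, c.fp + c.tn, "FPR"),
    )


def roc_pr_auc(labels, scores) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points (fpr, tpr), PR points (recall, precision), trapezoid AUC."""
    labels, scores = _validate_scores(labels, scores)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present to compute curves")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    precision, recall, _ = precision_recall_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    roc_points = np.column_stack([fpr, tpr])
    pr_points = np.column_stack([recall[::-1], precision[::-1]])
    return roc_points, pr_points, auc


def equilibrium_point(labels, scores) -> float:
    """Recall value where the PR curve crosses precision == recall."""
    _, pr_points, _ = roc_pr_auc(labels, scores)
    diffs = pr_points[:, 1] - pr_points[:, 0]
    idx = int(np.argmin(np.abs(diffs)))
    return float(pr_points[idx, 0])


def stratified_folds(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (train.copy(), test.copy())
        for train, test in splitter.split(np.zeros(len(labels)), labels)
    ]


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    pooled_labels: np.ndarray | None = None
    pooled_scores: np.ndarray | None = None
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = self.fold_reports[0].as_dict().keys()
        for key in keys:
            vals = np.array([r.as_dict()[key] for r in self.fold_reports])
            self.mean[key] = float(vals.mean())
            self.std[key] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def cross_validate(
    catalog: AssociationCatalog,
    msim: SimilarityMatrix,
    dsim: SimilarityMatrix,
    ae_config: AEConfig,
    mlp_config: MLPConfig,
    n_folds: int = 5,
    n_clusters: int = 23,
    seed: int = 0,
    threshold: float = 0.5,
) -> CrossValidationResult:
    """Stratified k-fold evaluation of the full latent-feature pipeline.

    Similarity matrices are taken as given (they derive from the full known
    topology). Within each fold the test-fold positives are zeroed out of
    MD before the autoencoders run, so a test edge never informs its own
    latent features; the MLP is trained on the training pairs only.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    from .io_formats import build_adjacency

    md = build_adjacency(catalog)
    negatives = sample_negatives(md, n_clusters=n_clusters, seed=seed)
    samples = make_sample_set(md, negatives)
    folds = stratified_folds(samples.labels, n_folds, seed)
    reports: list[MetricsReport] = []
    pooled_labels: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        if samples.labels[train_idx].sum() == 0 or samples.labels[test_idx].sum() == 0:
            raise ValueError(f"fold {fold_idx} has no positive pairs")
        masked = md.values.astype(np.int8).copy()
        for idx in test_idx:
            i, j = samples.pairs[idx]
            masked[i, j] = 0
        masked_md = AdjacencyMatrix(
            values=masked, row_names=md.row_names, col_names=md.col_names
        )
        m_latent, d_latent = _train_latents(masked_md, ae_config)
        table = fuse_features(m_latent, msim.values, d_latent, dsim.values, samples)
        model = mlp.fit(
            table.matrix[train_idx], samples.labels[train_idx], mlp_config
        )
        scores = mlp.predict_proba(model, table.matrix[test_idx])
        pooled_labels.append(samples.labels[test_idx])
        pooled_scores.append(scores)
        counts = confusion(samples.labels[test_idx], scores, threshold)
        _, _, auc = roc_pr_auc(samples.labels[test_idx], scores)
        report = metrics(counts)
        reports.append(
            MetricsReport(**{**report.as_dict(), "auc": auc})
        )
        logger.info("fold %d: auc=%.4f acc=%.4f", fold_idx, auc, report.accuracy)
    return CrossValidationResult(
        fold_reports=reports,
        pooled_labels=np.concatenate(pooled_labels),
        pooled_scores=np.concatenate(pooled_scores),
    )


def _train_latents(
    md: AdjacencyMatrix, ae_config: AEConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent sparse AEs: rows of MD and rows of MD^T (seed, seed+1)."""
    from dataclasses import replace

    x_m = md.values.astype(float)
    x_d = x_m.T.copy()
    model_m, _ = autoencoder.train_autoencoder(x_m, ae_config)
    model_d, _ = autoencoder.train_autoencoder(
        x_d, replace(ae_config, seed=ae_config.seed + 1)
    )
    return autoencoder.encode(model_m, x_m), autoencoder.encode(model_d, x_d)
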