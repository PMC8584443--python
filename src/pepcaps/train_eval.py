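"""Training loop, cross-validation and evaluation indices.

The continuous score of a peptide is the norm of the detectable output
capsule; the hard decision compares the two capsule norms (ties go to
undetectable). Reported indices: trapezoidal ROC-AUC, standard accuracy
(TP+TN)/N, sensitivity TP/(TP+FN), specificity TN/(FP+TN), precision
TP/(TP+FP) and F-score (harmonic mean of precision and sensitivity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .config import NetworkConfig
from .data_io import Dataset
from .features import PropertyTable, featurize_peptides
from .model import CapsNetCBAM, classify, margin_loss

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "metrics_from_counts",
    "roc_points",
    "pr_points",
    "auc_score",
    "train",
    "evaluate",
    "cross_validate",
]

METRICS = ("auc", "accuracy", "specificity", "sensitivity", "precision", "f_score")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(labels: np.ndarray, preds: np.ndarray) -> ConfusionCounts:
    labels = np.asarray(labels).astype(bool)
    preds = np.asarray(preds).astype(bool)
    return ConfusionCounts(
        tp=int((preds & labels).sum()),
        fp=int((preds & ~labels).sum()),
        tn=int((~preds & ~labels).sum()),
        fn=int((~preds & labels).sum()),
    )


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Threshold metrics from a confusion table.

    ``precision`` is TP/(TP+FP); ``accuracy`` is the conventional
    (TP+TN)/N. F-score is the harmonic mean of precision and sensitivity.
    """
    precision = _safe_div(c.tp, c.tp + c.fp)
    sensitivity = _safe_div(c.tp, c.tp + c.fn)
    return {
        "accuracy": _safe_div(c.tp + c.tn, c.total),
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": _safe_div(c.tn, c.fp + c.tn),
        "f_score": _safe_div(2 * precision * sensitivity, precision + sensitivity),
    }


def _check_two_class(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("ROC/PR need at least one positive and one negative label")


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC as an (m, 2) array of (FPR, TPR) from (0,0) to (1,1)."""
    _check_two_class(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def pr_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Precision-recall points as an (m, 2) array of (recall, precision)."""
    _check_two_class(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return np.column_stack([recall, precision])[::-1]


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal area under the empirical ROC curve."""
    pts = roc_points(scores, labels)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


@dataclass
class MetricReport:
    """Per-fold metrics plus their mean and standard deviation.

    ``curves`` optionally carries averaged ROC/PR points (columns x, y).
    """

    per_fold: list[dict[str, float]]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    loss_traces: list[list[float]] = field(default_factory=list)
    curves: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            keys = self.per_fold[0].keys()
            vals = {k: np.array([f[k] for f in self.per_fold], dtype=float) for k in keys}
            self.mean = {k: float(np.nanmean(v)) for k, v in vals.items()}
            self.sd = {k: float(np.nanstd(v)) for k, v in vals.items()}

    def to_dict(self) -> dict:
        return {"per_fold": self.per_fold, "mean": self.mean, "sd": self.sd}


def train(
    model: CapsNetCBAM,
    bio: np.ndarray,
    codes: np.ndarray,
    labels: np.ndarray,
    epochs: int | None = None,
    seed: int | None = None,
) -> list[float]:
    """Train with Adam on margin loss; returns the mean loss per epoch.

    Shuffling is driven by ``seed`` (defaults to the model config's seed);
    ``epochs=0`` leaves the model untouched and returns an empty trace.
    If the model has no feature scaler yet, one is fit on this training set.
    """
    cfg = model.cfg
    epochs = cfg.epochs if epochs is None else epochs
    if len(bio) == 0:
        raise ValueError("empty training set")
    if model.scaler is None:
        model.fit_scaler(bio)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    opt = model.make_optimizer()
    labels = np.asarray(labels)
    trace: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(len(bio))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            v, _ = model.forward(bio[sel], codes[sel])
            loss = margin_loss(v, labels[sel], cfg.m_pos, cfg.m_neg, cfg.lam)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
        logger.info("epoch %d/%d: mean margin loss %.4f", epoch + 1, epochs, trace[-1])
    return trace


def evaluate(
    model: CapsNetCBAM,
    bio: np.ndarray,
    codes: np.ndarray,
    labels: np.ndarray,
) -> dict[str, float]:
    """Score a labelled set: AUC over detectable-capsule norms plus count metrics.

    A single-class test set gets ``auc = nan`` (undefined), with a warning.
    """
    labels = np.asarray(labels)
    norms = model.scores(bio, codes)
    preds = classify(norms)
    out = metrics_from_counts(confusion_counts(labels, preds))
    if labels.min() == labels.max():
        logger.warning("single-class test set: AUC undefined")
        out["auc"] = float("nan")
    else:
        out["auc"] = auc_score(norms[:, 0], labels)
    return out


def _mean_curve(curves: list[np.ndarray], n_grid: int = 101) -> np.ndarray:
    grid = np.linspace(0, 1, n_grid)
    ys = [np.interp(grid, c[:, 0], c[:, 1]) for c in curves]
    return np.column_stack([grid, np.mean(ys, axis=0)])


def cross_validate(
    ds: Dataset,
    cfg: NetworkConfig,
    table: PropertyTable | None = None,
    k: int | None = None,
) -> MetricReport:
    """Stratified k-fold training/evaluation using the dataset's assignments.

    Each fold trains a fresh model (seeded from the config seed plus the
    fold index) on the other folds; the report aggregates fold metrics and
    fold-averaged ROC/PR curves.
    """
    if ds.split_assignment is None:
        raise ValueError("dataset has no split assignment; call make_splits first")
    folds = np.unique(ds.split_assignment)
    if k is not None and len(folds) != k:
        raise ValueError(f"expected {k} folds, found {len(folds)}")
    bio, codes = featurize_peptides(ds.peptides, table, cfg.kurtosis_sigma2)
    labels = ds.labels

    per_fold, traces, rocs, prs = [], [], [], []
    for fold in folds:
        test = ds.split_assignment == fold
        train_mask = ~test
        fold_cfg = NetworkConfig.from_dict({**cfg.to_dict(), "seed": cfg.seed + int(fold)})
        model = CapsNetCBAM(fold_cfg)
        traces.append(
            train(model, bio[train_mask], codes[train_mask], labels[train_mask])
        )
        per_fold.append(evaluate(model, bio[test], codes[test], labels[test]))
        if labels[test].min() != labels[test].max():
            norms = model.scores(bio[test], codes[test])
            rocs.append(roc_points(norms[:, 0], labels[test]))
            prs.append(pr_points(norms[:, 0], labels[test]))
        logger.info("fold %s: %s", fold, per_fold[-1])

    curves = {}
    if rocs:
        curves["roc"] = _mean_curve(rocs)
        curves["pr"] = _mean_curve(prs)
    return MetricReport(per_fold=per_fold, loss_traces=traces, curves=curves)
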