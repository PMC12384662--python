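"""Evaluation protocol: per-case training, confusion-matrix metrics, and
the window-length sweep.

The protocol mirrors the study design: segments are shuffled and split
7:3 (stratified), three stratified folds are formed over the 70% training
portion, one model is trained per fold (fitting on two thirds, validating
on the held-out third), and every fold-model is evaluated once on the
shared 30% test set. Accuracy, sensitivity and specificity are reported as
mean ± standard deviation across the three fold-models, in percent.

For binary cases the positive class is the ictal one (class index 1, set
E in the Bonn pairings) — the seizure-detection convention. For three
classes, sensitivity and specificity are macro-averages of one-vs-rest
values.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bonn import DatasetCase, Recording, build_case
from .estimator import CapsNetClassifier
from .preprocess import (
    SegmentationConfig,
    factorize_length,
    make_splits,
    segment_labeled_recordings,
    standardize,
)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "confusion_matrix",
    "confusion_metrics",
    "run_case",
    "time_interval_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimisation schedule (Adam at the reference hyperparameters)."""

    learning_rate: float = 5e-4
    batch_size: int = 32
    epochs: int = 400
    max_epochs: int = 1000
    seed: int = 0
    class_weights: tuple | None = None
    loss_threshold: float | None = None
    routing_iters: int = 3

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("invalid optimisation hyperparameters")
        if self.epochs > self.max_epochs:
            raise ValueError("epochs exceeds max_epochs")


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K matrix, rows = actual class, columns = predicted class."""
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(np.asarray(y_true), np.asarray(y_pred)):
        cm[int(t), int(p)] += 1
    return cm


def confusion_metrics(cm: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in percent from a confusion
    matrix with rows = actual.

    Binary: class 1 is positive. Multiclass: macro one-vs-rest averages;
    classes with no actual (or no negative) samples are excluded from the
    corresponding average with a warning.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] < 2:
        raise ValueError("confusion matrix must be square, K >= 2")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    accuracy = 100.0 * np.trace(cm) / total

    k = cm.shape[0]
    if k == 2:
        tp, fn = cm[1, 1], cm[1, 0]
        tn, fp = cm[0, 0], cm[0, 1]
        sens = 100.0 * tp / (tp + fn) if (tp + fn) else np.nan
        spec = 100.0 * tn / (tn + fp) if (tn + fp) else np.nan
        if np.isnan(sens) or np.isnan(spec):
            warnings.warn("a class has no actual samples; metric undefined")
        return float(accuracy), float(sens), float(spec)

    sens_parts, spec_parts = [], []
    for c in range(k):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"class {c} has no actual samples; excluded from macro sensitivity")
        else:
            sens_parts.append(tp / (tp + fn))
        if tn + fp == 0:
            warnings.warn(f"class {c} has no actual negatives; excluded from macro specificity")
        else:
            spec_parts.append(tn / (tn + fp))
    return (
        float(accuracy),
        float(100.0 * np.mean(sens_parts)),
        float(100.0 * np.mean(spec_parts)),
    )


@dataclass
class MetricsReport:
    """Cross-validated metrics for one dataset case (percent)."""

    case: str
    accuracy_mean: float
    accuracy_std: float
    sensitivity_mean: float
    sensitivity_std: float
    specificity_mean: float
    specificity_std: float
    fold_confusions: list
    fold_accuracies: list
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["fold_confusions"] = [
            np.asarray(c).tolist() for c in self.fold_confusions
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": ["accuracy", "sensitivity", "specificity"],
                "mean_pct": [
                    self.accuracy_mean,
                    self.sensitivity_mean,
                    self.specificity_mean,
                ],
                "std_pct": [
                    self.accuracy_std,
                    self.sensitivity_std,
                    self.specificity_std,
                ],
            }
        )

    def __str__(self) -> str:
        return (
            f"{self.case}: acc {self.accuracy_mean:.2f}±{self.accuracy_std:.2f}% "
            f"sens {self.sensitivity_mean:.2f}±{self.sensitivity_std:.2f}% "
            f"spec {self.specificity_mean:.2f}±{self.specificity_std:.2f}%"
        )


def run_case(
    recordings_by_set: dict[str, list[Recording]],
    case: DatasetCase,
    seg_cfg: SegmentationConfig | None = None,
    train_cfg: TrainConfig | None = None,
    input_hw: tuple[int, int] | None = None,
    return_models: bool = False,
):
    """Execute the full protocol for one dataset case.

    segment -> standardize (train statistics only) -> 7:3 split -> 3-fold
    CV over train -> one model per fold -> evaluate each fold-model on the
    shared test set -> mean ± std metrics.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    train_cfg = train_cfg or TrainConfig()

    labeled = build_case(recordings_by_set, case)
    segments = segment_labeled_recordings(labeled, seg_cfg)
    y = np.array([s.class_idx for s in segments])
    logger.info("case %s: %d segments of %d points", case.name, y.size, seg_cfg.window_pts)

    plan = make_splits(y, seed=train_cfg.seed)
    X, mean, sd = standardize(segments, plan.train_idx)
    hw = input_hw or factorize_length(seg_cfg.window_pts)

    fold_cms, fold_accs, models, histories = [], [], [], []
    for fold_no, (fit_idx, val_idx) in enumerate(plan.folds):
        clf = CapsNetClassifier(
            input_hw=hw,
            routing_iters=train_cfg.routing_iters,
            learning_rate=train_cfg.learning_rate,
            batch_size=train_cfg.batch_size,
            epochs=train_cfg.epochs,
            loss_threshold=train_cfg.loss_threshold,
            class_weight=train_cfg.class_weights,
            random_state=train_cfg.seed + fold_no,
        )
        clf.fit(X[fit_idx], y[fit_idx], validation_data=(X[val_idx], y[val_idx]))
        pred = clf.predict(X[plan.test_idx])
        cm = confusion_matrix(y[plan.test_idx], pred, case.n_classes)
        acc, sens, spec = confusion_metrics(cm)
        logger.info("fold %d: test acc %.2f%% sens %.2f%% spec %.2f%%",
                    fold_no, acc, sens, spec)
        fold_cms.append(cm)
        fold_accs.append(acc)
        models.append(clf)
        histories.append(clf.history_)

    per_fold = np.array([confusion_metrics(cm) for cm in fold_cms])
    report = MetricsReport(
        case=case.name,
        accuracy_mean=float(per_fold[:, 0].mean()),
        accuracy_std=float(per_fold[:, 0].std()),
        sensitivity_mean=float(per_fold[:, 1].mean()),
        sensitivity_std=float(per_fold[:, 1].std()),
        specificity_mean=float(per_fold[:, 2].mean()),
        specificity_std=float(per_fold[:, 2].std()),
        fold_confusions=fold_cms,
        fold_accuracies=fold_accs,
        config={
            "window_pts": seg_cfg.window_pts,
            "input_hw": list(hw),
            "standardize_mean": mean,
            "standardize_sd": sd,
            "epochs": train_cfg.epochs,
            "learning_rate": train_cfg.learning_rate,
            "batch_size": train_cfg.batch_size,
            "routing_iters": train_cfg.routing_iters,
            "seed": train_cfg.seed,
        },
    )
    if return_models:
        return report, models, histories, plan
    return report


def time_interval_sweep(
    recordings_by_set: dict[str, list[Recording]],
    case: DatasetCase,
    intervals_s: tuple[float, ...] = (0.6, 0.8, 1.0, 1.2, 1.4),
    train_cfg: TrainConfig | None = None,
    fs: float | None = None,
    selected_s: float = 1.0,
) -> pd.DataFrame:
    """Re-run the case for several window lengths; returns a table with
    one row per interval (the 1.0 s operating point is flagged)."""
    rows = []
    for interval in intervals_s:
        seg_cfg = (
            SegmentationConfig(window_s=interval, fs=fs)
            if fs is not None
            else SegmentationConfig(window_s=interval)
        )
        report = run_case(recordings_by_set, case, seg_cfg, train_cfg)
        rows.append(
            {
                "interval_s": interval,
                "window_pts": seg_cfg.window_pts,
                "accuracy_mean_pct": report.accuracy_mean,
                "accuracy_std_pct": report.accuracy_std,
                "selected": interval == selected_s,
            }
        )
        logger.info("interval %.1f s: acc %.2f%%", interval, report.accuracy_mean)
    return pd.DataFrame(rows)
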