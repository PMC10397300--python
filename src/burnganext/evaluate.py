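"""Training, fivefold cross-validation and the metric suite.

Metrics follow the one-vs-rest confusion-matrix definitions: accuracy
(TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP), recall = sensitivity
TP/(TP+FN), F1 = 2*P*R/(P+R), and specificity TN/(TN+FP).  A
``literal`` mode preserves the alternative specificity definition
TN/(TP+TN) for auditability.  All values are percentages; zero-denominator
cells are reported as NaN with an ``undefined`` flag rather than zero.

Fold assignment is stratified (per-class 80/20) so small datasets never
produce empty-class validation folds; when augmentation is requested it is
applied to the training split only, and the policy is recorded in the run
log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from sklearn import metrics as _skm
from sklearn.model_selection import KFold, StratifiedKFold

from . import data as _data
from .autograd import Tensor, backward, softmax_cross_entropy
from .config import ModelConfig, TrainingHyperparams
from .data import AugmentationSet, ImageRecord, augment, records_to_arrays
from .errors import ConfigurationError, InputError, UsageError
from .model import NetworkModel, build_model
from .optim import make_optimizer

__all__ = [
    "FoldSplit",
    "MetricsReport",
    "kfold_split",
    "holdout_split",
    "confusion_matrix",
    "metrics_from_cm",
    "roc_curve_ovr",
    "train_model",
    "run_cv_experiment",
    "CVResult",
]

METRIC_COLUMNS = ["precision", "recall", "f1", "sensitivity", "specificity", "accuracy"]
TABLE_COLUMNS = ["Precision", "Recall", "F1-score", "Sensitivity", "Specificity", "Accuracy"]


@dataclasses.dataclass(frozen=True)
class FoldSplit:
    index: int  # 1-based fold number
    train_ids: Tuple[int, ...]
    val_ids: Tuple[int, ...]


def kfold_split(
    ids: Sequence, labels: Optional[Sequence] = None, k: int = 5, seed: int = 0
) -> List[FoldSplit]:
    """Deterministic k-fold partition (stratified when labels are given)."""
    ids = list(ids)
    if len(ids) < k:
        raise InputError(f"need at least k={k} items, got {len(ids)}")
    if labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        gen = splitter.split(np.zeros(len(ids)), np.asarray(labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        gen = splitter.split(np.zeros(len(ids)))
    return [
        FoldSplit(
            index=i + 1,
            train_ids=tuple(ids[j] for j in tr),
            val_ids=tuple(ids[j] for j in va),
        )
        for i, (tr, va) in enumerate(gen)
    ]


def holdout_split(
    ids: Sequence, labels: Optional[Sequence] = None, seed: int = 0, k: int = 5
) -> FoldSplit:
    """A single stratified 80/20 train/validation split (fold 1 of k)."""
    return kfold_split(ids, labels, k=k, seed=seed)[0]


# ---------------------------------------------------------------------------
# confusion matrix and metric formulas
# ---------------------------------------------------------------------------

def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int], k: int) -> np.ndarray:
    """k x k counts; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise InputError("label vectors must have equal length")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= k or y_pred.min() < 0 or y_pred.max() >= k
    ):
        raise InputError(f"labels must lie in 0..{k - 1}")
    cm = np.zeros((k, k), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclasses.dataclass
class MetricsReport:
    """Per-class and macro-averaged statistics, in percent."""

    per_class: Dict[int, Dict[str, float]]
    macro: Dict[str, float]
    overall_accuracy: float
    undefined: List[Tuple[int, str]]
    mode: str = "standard"

    def as_row(self) -> Dict[str, float]:
        return dict(self.macro)


def metrics_from_cm(cm: np.ndarray, mode: str = "standard") -> MetricsReport:
    """The six confusion-matrix statistics, one-vs-rest per class.

    ``mode='standard'`` uses specificity TN/(TN+FP); ``mode='literal'``
    uses the alternative TN/(TP+TN).
    """
    if mode not in ("standard", "literal"):
        raise UsageError(f"unknown metrics mode {mode!r}")
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise InputError("confusion matrix has no observations")
    k = cm.shape[0]
    per_class: Dict[int, Dict[str, float]] = {}
    undefined: List[Tuple[int, str]] = []

    def ratio(num, den, cls, name):
        if den == 0:
            undefined.append((cls, name))
            return float("nan")
        return 100.0 * num / den

    for i in range(k):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = int(total - tp - fn - fp)
        pre = ratio(tp, tp + fp, i, "precision")
        rec = ratio(tp, tp + fn, i, "recall")
        if np.isnan(pre) or np.isnan(rec) or (pre + rec) == 0:
            if not (np.isnan(pre) or np.isnan(rec)):
                undefined.append((i, "f1"))
            f1 = float("nan")
        else:
            f1 = 2 * pre * rec / (pre + rec)
        sen = ratio(tp, tp + fn, i, "sensitivity")
        if mode == "standard":
            spec = ratio(tn, tn + fp, i, "specificity")
        else:
            spec = ratio(tn, tp + tn, i, "specificity")
        acc = ratio(tp + tn, tp + tn + fp + fn, i, "accuracy")
        per_class[i] = {
            "precision": pre,
            "recall": rec,
            "f1": f1,
            "sensitivity": sen,
            "specificity": spec,
            "accuracy": acc,
        }
    macro = {}
    for m in METRIC_COLUMNS:
        vals = [per_class[i][m] for i in range(k) if not np.isnan(per_class[i][m])]
        macro[m] = float(np.mean(vals)) if vals else float("nan")
    overall = 100.0 * np.trace(cm) / total
    return MetricsReport(per_class, macro, float(overall), undefined, mode)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float  # NaN when undefined (single-class truth)


def roc_curve_ovr(y_true: Sequence[int], scores: np.ndarray) -> List[ROCCurve]:
    """One-vs-rest ROC points and trapezoid AUC for each class column."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = np.column_stack([1 - scores, scores])
    if scores.min() < 0 or scores.max() > 1:
        raise InputError("class scores must lie in [0, 1]")
    curves = []
    for c in range(scores.shape[1]):
        pos = y_true == c
        if pos.all() or (~pos).all():
            curves.append(
                ROCCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]), float("nan"))
            )
            continue
        fpr, tpr, _ = _skm.roc_curve(pos.astype(int), scores[:, c])
        curves.append(ROCCurve(fpr, tpr, float(_skm.auc(fpr, tpr))))
    return curves


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_eval(model: NetworkModel, x: np.ndarray, y: np.ndarray, batch: int = 64):
    probs = model.predict_proba(x, batch_size=batch)
    loss = float(-np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)).mean())
    acc = float((probs.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(
    model: NetworkModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    params: TrainingHyperparams,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    verbose: bool = False,
) -> Dict[str, list]:
    """Mini-batch training; returns the per-epoch loss/accuracy history."""
    params.validate()
    if int(y_train.max(initial=0)) >= model.config.num_classes:
        raise ConfigurationError(
            f"labels reach {int(y_train.max())} but the model head has "
            f"{model.config.num_classes} classes"
        )
    rng = np.random.default_rng(params.seed)
    opt = make_optimizer(
        params.optimizer, model.parameters(), params.learning_rate, params.momentum
    )
    n = len(x_train)
    history: Dict[str, list] = {
        "epoch": [], "train_loss": [], "train_acc": [],
        "val_loss": [], "val_acc": [], "steps": [],
    }
    steps_total = 0
    for epoch in range(1, params.epochs + 1):
        model.train()
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for start in range(0, n, params.batch_size):
            idx = order[start: start + params.batch_size]
            xb = Tensor(x_train[idx])
            logits = model.forward_logits(xb)
            loss = softmax_cross_entropy(logits, y_train[idx])
            preds = logits.data.argmax(axis=1)
            hits += int((preds == y_train[idx]).sum())
            seen += len(idx)
            losses.append(float(loss.data))
            opt.zero_grad()
            backward(loss)
            opt.step()
            steps_total += 1
        model.eval()
        vl = va = float("nan")
        if x_val is not None and len(x_val):
            vl, va = _batch_eval(model, x_val, y_val)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / max(seen, 1))
        history["val_loss"].append(vl)
        history["val_acc"].append(va)
        history["steps"].append(steps_total)
        if verbose:
            print(
                f"epoch {epoch:3d}  loss {history['train_loss'][-1]:.4f}  "
                f"acc {history['train_acc'][-1]:.3f}  val_acc {va:.3f}"
            )
    return history


# ---------------------------------------------------------------------------
# cross-validation experiment
# ---------------------------------------------------------------------------

def holdout_training_run(
    records: Sequence[ImageRecord],
    task: str,
    model_config: ModelConfig,
    hyperparams: TrainingHyperparams,
    seed: int = 0,
    track_validation: bool = False,
) -> Dict:
    """Train one task on a stratified 80/20 split and score the held-out 20%.

    Returns the held-out accuracy (percent), the metric report, the training
    history and a run log.  ``track_validation`` additionally evaluates the
    validation set after every epoch (slower; the history then carries the
    accuracy/loss curves).
    """
    n_classes = _task_classes(task)
    if model_config.num_classes != n_classes:
        raise ConfigurationError(
            f"task {task!r} needs a {n_classes}-way head, config has "
            f"{model_config.num_classes}"
        )
    labels = _data.label_codes([r.label for r in records], task)
    split = holdout_split(range(len(records)), labels, seed=seed)
    x, y = records_to_arrays(records, task)
    tr, va = list(split.train_ids), list(split.val_ids)
    model = build_model(model_config, seed=seed + 1)
    t0 = time.time()
    hist = train_model(
        model, x[tr], y[tr], hyperparams,
        x[va] if track_validation else None, y[va] if track_validation else None,
    )
    model.eval()
    preds = model.predict(x[va])
    cm = confusion_matrix(y[va], preds, n_classes)
    report = metrics_from_cm(cm)
    accuracy = 100.0 * float((preds == y[va]).mean())
    run_log = {
        "task": task,
        "seed": seed,
        "n_train": len(tr),
        "n_val": len(va),
        "model_stem_width": model_config.stages[0].ops[0].out_channels,
        "model_variant": "half_width" if model_config.stages[0].ops[0].out_channels == 128
        else "custom",
        "wall_seconds": time.time() - t0,
        "hyperparams": dataclasses.asdict(hyperparams),
    }
    return {
        "accuracy": accuracy,
        "report": report,
        "confusion": cm,
        "history": hist,
        "model": model,
        "run_log": run_log,
    }


@dataclasses.dataclass
class CVResult:
    task: str
    fold_reports: List[MetricsReport]
    fold_cms: List[np.ndarray]
    fold_rocs: List[List[ROCCurve]]
    histories: List[Dict[str, list]]
    average: Dict[str, float]
    run_log: Dict

    def table(self) -> pd.DataFrame:
        """Fold rows plus the average row, in the standard reporting layout."""
        rows = []
        for rep in self.fold_reports:
            rows.append([rep.macro[m] for m in METRIC_COLUMNS])
        rows.append([self.average[m] for m in METRIC_COLUMNS])
        index = [f"Fold{i + 1}" for i in range(len(self.fold_reports))] + ["Average"]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS, index=index)


def _task_classes(task: str) -> int:
    if task == "degree":
        return 3
    if task == "graft":
        return 2
    raise UsageError(f"unknown task {task!r}; choose 'degree' or 'graft'")


def run_cv_experiment(
    records: Sequence[ImageRecord],
    task: str,
    model_config: ModelConfig,
    hyperparams: TrainingHyperparams,
    k: int = 5,
    seed: int = 0,
    augmentations: Optional[AugmentationSet] = None,
    metrics_mode: str = "standard",
    verbose: bool = False,
) -> CVResult:
    """Stratified k-fold cross-validation of one classification task.

    Augmentation, when given, expands the training split only (validation
    images are never augmented copies of training images); the policy is
    recorded in the run log.
    """
    n_classes = _task_classes(task)
    if model_config.num_classes != n_classes:
        raise ConfigurationError(
            f"task {task!r} needs a {n_classes}-way head, config has "
            f"{model_config.num_classes}"
        )
    labels = _data.label_codes([r.label for r in records], task)
    folds = kfold_split(range(len(records)), labels, k=k, seed=seed)
    reports, cms, rocs, histories = [], [], [], []
    for fold in folds:
        train_recs = [records[i] for i in fold.train_ids]
        if augmentations is not None:
            train_recs = [a for r in train_recs for a in augment(r, augmentations)]
        xt, yt = records_to_arrays(train_recs, task)
        val_recs = [records[i] for i in fold.val_ids]
        xv, yv = records_to_arrays(val_recs, task)
        model = build_model(model_config, seed=seed + fold.index)
        fold_params = dataclasses.replace(hyperparams, seed=hyperparams.seed + fold.index)
        t0 = time.time()
        hist = train_model(model, xt, yt, fold_params, xv, yv, verbose=verbose)
        model.eval()
        probs = model.predict_proba(xv)
        preds = probs.argmax(axis=1)
        cm = confusion_matrix(yv, preds, n_classes)
        reports.append(metrics_from_cm(cm, metrics_mode))
        cms.append(cm)
        rocs.append(roc_curve_ovr(yv, probs))
        hist["wall_seconds"] = [time.time() - t0]
        histories.append(hist)
    average = {
        m: float(np.nanmean([rep.macro[m] for rep in reports])) for m in METRIC_COLUMNS
    }
    cfg_yaml = yaml.safe_dump(model_config.to_dict(), sort_keys=False)
    run_log = {
        "task": task,
        "k": k,
        "seed": seed,
        "n_records": len(records),
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "augmentation_policy": "train_split_only" if augmentations else "none",
        "hyperparams": dataclasses.asdict(hyperparams),
    }
    return CVResult(task, reports, cms, rocs, histories, average, run_log)
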