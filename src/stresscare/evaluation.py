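"""Evaluation metrics and the subject-wise cross-validation harness.

Metrics follow the standard one-vs-rest confusion-matrix definitions: for
class i with true/false positives and negatives TP, FP, TN, FN,

    accuracy   = (TP + TN) / (TP + FP + TN + FN)        (two-class form;
                 the multiclass generalisation is trace / total)
    precision  x_i = TP / (TP + FP)
    recall     y_i = TP / (TP + FN)
    macro F1   = (1/nc) * sum_i 2 x_i y_i / (x_i + y_i)

The class count nc is fixed by the task (2 or 3), not by the labels that
happen to occur: a class absent from a fold contributes an F1 of 0, which
keeps macro F1 comparable across folds.  The two-class task merges baseline
and amusement into a single non-stress class (stress keeps code 1).

Cross-validation is leave-one-subject-out (LOSO) by default: folds are whole
subjects, so no within-subject window ever appears on both sides of a split.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .model import (
    BranchModel,
    BranchSpec,
    GatedEnsemble,
    train_branch,
    train_gate,
)

logger = logging.getLogger(__name__)

TASK_CLASSES = {"two_class": 2, "three_class": 3}


def merge_two_class(labels: np.ndarray) -> np.ndarray:
    """Collapse {baseline, amusement} -> 0 (non-stress); stress stays 1."""
    labels = np.asarray(labels, dtype=int)
    return np.where(labels == 1, 1, 0)


def task_labels(labels: np.ndarray, task: str) -> np.ndarray:
    if task not in TASK_CLASSES:
        raise ValidationError(f"unknown task {task!r}")
    return merge_two_class(labels) if task == "two_class" else np.asarray(labels, int)


@dataclass
class ConfusionMatrix:
    """An nc x nc count matrix with one-vs-rest per-class statistics."""

    nc: int
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts).astype(float)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(float) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return float(self.total) - self.tp - self.fp - self.fn

    @property
    def precision(self) -> np.ndarray:
        """x_i = TP / (TP + FP); 0 where the class was never predicted."""
        denom = self.tp + self.fp
        return np.divide(self.tp, denom, out=np.zeros(self.nc), where=denom > 0)

    @property
    def recall(self) -> np.ndarray:
        """y_i = TP / (TP + FN); 0 where the class never occurred."""
        denom = self.tp + self.fn
        return np.divide(self.tp, denom, out=np.zeros(self.nc), where=denom > 0)


def confusion(y_true: np.ndarray, y_pred: np.ndarray, nc: int) -> ConfusionMatrix:
    """Build the nc x nc confusion matrix (rows = true, columns = predicted)."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValidationError("empty label arrays")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.min() < 0 or arr.max() >= nc:
            raise ValidationError(f"{name} contains labels outside [0, {nc})")
    counts = np.zeros((nc, nc), dtype=int)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(nc, counts)


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples: trace / total.

    For nc = 2 this equals (TP + TN) / (TP + FP + TN + FN) of either class.
    """
    if cm.total == 0:
        raise ValidationError("accuracy of an empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean over the task's nc classes of 2xy/(x+y).

    A class with precision + recall = 0 (including one absent from the
    data) contributes 0.
    """
    x, y = cm.precision, cm.recall
    denom = x + y
    f1 = np.divide(2.0 * x * y, denom, out=np.zeros(cm.nc), where=denom > 0)
    return float(f1.mean())


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------


@dataclass
class SubjectFeatures:
    """All feature tables for one subject, aligned row-for-row by segment."""

    subject_id: str
    labels: np.ndarray  # raw 3-state segment labels
    context: pd.DataFrame
    branch_tables: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.context) != n or any(len(t) != n for t in self.branch_tables.values()):
            raise ValidationError(
                f"subject {self.subject_id}: feature tables not aligned with labels"
            )


@dataclass
class EvaluationReport:
    task: str
    protocol: str
    accuracy: float
    macro_f1: float
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_f1: list[float]
    folds: list[dict]
    branch_metrics: dict[str, dict]  # solo pooled accuracy / macro F1 per branch
    config_fingerprint: str
    n_segments: int

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "protocol": self.protocol,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class_precision": self.per_class_precision,
            "per_class_recall": self.per_class_recall,
            "per_class_f1": self.per_class_f1,
            "folds": self.folds,
            "branch_metrics": self.branch_metrics,
            "config_fingerprint": self.config_fingerprint,
            "n_segments": self.n_segments,
        }


def _fingerprint(obj: dict) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


def _concat_subject(subjects: list[SubjectFeatures], specs: list[BranchSpec]):
    labels = np.concatenate([s.labels for s in subjects])
    context = pd.concat([s.context for s in subjects], ignore_index=True)
    branch_tables = {
        sp.branch_id: pd.concat(
            [s.branch_tables[sp.branch_id] for s in subjects], ignore_index=True
        )
        for sp in specs
    }
    return labels, context, branch_tables


def _with_labels(table: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    out = table.copy()
    out["label"] = labels
    return out


def derive_gate_supervision(
    train_subjects: list[SubjectFeatures],
    specs: list[BranchSpec],
    branch_backends: dict[str, str],
    task: str,
    seed: int,
    n_internal_folds: int = 3,
) -> np.ndarray:
    """Label each training segment with the branch that classifies it best.

    Branch correctness is measured out-of-sample: training subjects are
    grouped into internal folds and each branch predicts the subjects it was
    not fitted on.  Ties (equal correctness) go to the branch with fewer
    modalities — the cheaper sensor set — then to registration order.
    """
    n_sub = len(train_subjects)
    k = min(n_internal_folds, n_sub)
    order = sorted(specs, key=lambda sp: (len(sp.modalities), specs.index(sp)))
    rank = {sp.branch_id: i for i, sp in enumerate(order)}  # lower = preferred

    n_total = sum(len(s.labels) for s in train_subjects)
    correct = np.zeros((n_total, len(specs)), dtype=float)
    offsets = np.cumsum([0] + [len(s.labels) for s in train_subjects])

    fold_of = np.arange(n_sub) % k
    for f in range(k):
        fit_subj = [s for i, s in enumerate(train_subjects) if fold_of[i] != f]
        val_idx = [i for i in range(n_sub) if fold_of[i] == f]
        if not fit_subj or not val_idx:
            continue
        fit_labels, _, fit_tables = _concat_subject(fit_subj, specs)
        y_fit = task_labels(fit_labels, task)
        for j, sp in enumerate(specs):
            try:
                model = train_branch(
                    sp,
                    branch_backends[sp.branch_id],
                    _with_labels(fit_tables[sp.branch_id], y_fit),
                    seed,
                )
            except ValidationError:
                continue  # single-class internal fold: no evidence from it
            for i in val_idx:
                s = train_subjects[i]
                y_val = task_labels(s.labels, task)
                pred = model.predict(s.branch_tables[sp.branch_id])
                correct[offsets[i] : offsets[i + 1], j] = (pred == y_val).astype(float)

    # best branch: max correctness, ties -> fewer modalities, then order
    tiebreak = np.array([rank[sp.branch_id] for sp in specs], dtype=float)
    score = correct - 1e-6 * tiebreak
    return np.argmax(score, axis=1)


def _subject_folds(subject_ids: list[str], protocol: str, n_folds: int) -> list[list[str]]:
    if protocol == "loso":
        return [[sid] for sid in subject_ids]
    if protocol == "kfold":
        k = min(n_folds, len(subject_ids))
        return [list(subject_ids[i::k]) for i in range(k)]
    raise ValidationError(f"unknown protocol {protocol!r}")


def cross_validate(
    subjects: list[SubjectFeatures],
    specs: list[BranchSpec],
    branch_backends: dict[str, str] | str,
    gate_backend: str,
    b: float,
    task: str = "two_class",
    seed: int = 0,
    protocol: str = "loso",
    n_folds: int = 5,
    fusion_method: str = "average",
    context_modality: str = "ACC",
) -> EvaluationReport:
    """Subject-wise cross-validation of the full gated ensemble.

    For every fold the branches and the gate are trained on the remaining
    subjects only, the held-out subjects are predicted at threshold ``b``,
    and predictions are pooled across folds.  Solo (ungated) per-branch
    predictions on the held-out data are pooled too, so branch and ensemble
    performance come from the same splits.
    """
    if len(subjects) < 2:
        raise ValidationError("cross-validation needs at least 2 subjects")
    if isinstance(branch_backends, str):
        branch_backends = {sp.branch_id: branch_backends for sp in specs}
    nc = TASK_CLASSES[task]
    class_codes = np.arange(nc)

    fingerprint = _fingerprint(
        {
            "task": task,
            "protocol": protocol,
            "b": b,
            "seed": seed,
            "fusion": fusion_method,
            "gate_backend": gate_backend,
            "branches": {sp.branch_id: list(sp.modalities) for sp in specs},
            "backends": branch_backends,
        }
    )

    by_id = {s.subject_id: s for s in subjects}
    folds = _subject_folds([s.subject_id for s in subjects], protocol, n_folds)

    pooled_true: list[np.ndarray] = []
    pooled_pred: list[np.ndarray] = []
    pooled_branch_pred: dict[str, list[np.ndarray]] = {sp.branch_id: [] for sp in specs}
    fold_reports = []

    for fold_ids in folds:
        test_subjects = [by_id[sid] for sid in fold_ids]
        train_subjects = [s for s in subjects if s.subject_id not in fold_ids]
        if any(len(s.labels) == 0 for s in test_subjects):
            warnings.warn(f"fold {fold_ids}: subject with zero segments skipped", stacklevel=2)
            continue

        train_labels, train_context, train_tables = _concat_subject(train_subjects, specs)
        y_train = task_labels(train_labels, task)
        if np.unique(y_train).size < nc:
            warnings.warn(
                f"fold {fold_ids}: training data lacks a task class", stacklevel=2
            )

        supervision = derive_gate_supervision(
            train_subjects, specs, branch_backends, task, seed
        )
        gate = train_gate(
            train_context,
            supervision,
            [sp.branch_id for sp in specs],
            gate_backend,
            seed,
            context_modality=context_modality,
        )
        branches = {}
        for sp in specs:
            model = train_branch(
                sp,
                branch_backends[sp.branch_id],
                _with_labels(train_tables[sp.branch_id], y_train),
                seed,
            )
            branches[sp.branch_id] = _pad_classes(model, class_codes)
        ensemble = GatedEnsemble(gate, branches, class_codes, fusion_method)

        test_labels, test_context, test_tables = _concat_subject(test_subjects, specs)
        y_test = task_labels(test_labels, task)
        y_pred = ensemble.predict_labels(test_context, test_tables, b)

        pooled_true.append(y_test)
        pooled_pred.append(y_pred)
        for sp in specs:
            pooled_branch_pred[sp.branch_id].append(
                branches[sp.branch_id].predict(test_tables[sp.branch_id])
            )
        cm = confusion(y_test, y_pred, nc)
        fold_reports.append(
            {
                "held_out": fold_ids,
                "n_segments": int(y_test.size),
                "accuracy": accuracy(cm),
                "macro_f1": macro_f1(cm),
            }
        )

    y_true = np.concatenate(pooled_true)
    y_pred = np.concatenate(pooled_pred)
    cm = confusion(y_true, y_pred, nc)
    x, y, = cm.precision, cm.recall
    denom = x + y
    per_f1 = np.divide(2 * x * y, denom, out=np.zeros(nc), where=denom > 0)

    branch_metrics = {}
    for sp in specs:
        bp = np.concatenate(pooled_branch_pred[sp.branch_id])
        bcm = confusion(y_true, bp, nc)
        branch_metrics[sp.branch_id] = {
            "accuracy": accuracy(bcm),
            "macro_f1": macro_f1(bcm),
        }

    return EvaluationReport(
        task=task,
        protocol=protocol,
        accuracy=accuracy(cm),
        macro_f1=macro_f1(cm),
        per_class_precision=[float(v) for v in x],
        per_class_recall=[float(v) for v in y],
        per_class_f1=[float(v) for v in per_f1],
        folds=fold_reports,
        branch_metrics=branch_metrics,
        config_fingerprint=fingerprint,
        n_segments=int(y_true.size),
    )


def _pad_classes(model: BranchModel, class_codes: np.ndarray) -> BranchModel:
    """Extend a branch trained on a label subset to the full task class list."""
    if np.array_equal(model.classes, class_codes):
        return model

    class _Padded:
        def __init__(self, inner, inner_classes, full):
            self.inner, self.inner_classes, self.full = inner, inner_classes, full

        def predict_proba(self, X):
            p = np.asarray(self.inner.predict_proba(X), dtype=float)
            out = np.zeros((p.shape[0], self.full.size))
            idx = np.searchsorted(self.full, self.inner_classes)
            out[:, idx] = p
            return out

    padded = _Padded(model.estimator, model.classes, class_codes)
    return BranchModel(model.spec, model.backend, padded, class_codes, model.columns, model.seed)
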