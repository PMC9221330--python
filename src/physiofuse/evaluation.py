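"""Cross-validation and report generation.

Two schemes: stratified 10-fold (windows of one subject may appear in both
train and test folds — inherent to the protocol being reproduced and noted
in the report) and leave-one-subject-out, which measures cross-person
generalization.  MSE is the mean squared difference of integer label codes
in the fixed behavior order; it is order-sensitive by construction.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import ensemble as ens
from .features import FeatureMatrix
from .model import BehaviorLabel
from .screening import SelectedFeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "EvalReport",
    "classification_report",
    "label_mse",
    "kfold_cv",
    "loo_subject_cv",
]

_N_CLASSES = len(BehaviorLabel)


@dataclass
class EvalReport:
    scheme: str
    per_class: pd.DataFrame  # index: behavior name; columns precision/recall/f1/support
    accuracy_mean: float
    accuracy_min: float
    mse: float
    confusion: np.ndarray  # 6x6 counts, rows = true
    per_fold: list[dict] = field(default_factory=list)
    note: str = ""

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "per_class": self.per_class.round(6).to_dict(orient="index"),
            "accuracy_mean": self.accuracy_mean,
            "accuracy_min": self.accuracy_min,
            "mse": self.mse,
            "confusion": self.confusion.tolist(),
            "per_fold": self.per_fold,
            "note": self.note,
        }


def classification_report(y_true: np.ndarray, y_pred: np.ndarray) -> pd.DataFrame:
    """Per-class precision/recall/F1 plus support, by the direct formulas.

    Zero-division cases yield 0 with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    rows = {}
    for lab in BehaviorLabel:
        tp = int(np.sum((y_true == lab) & (y_pred == lab)))
        fp = int(np.sum((y_true != lab) & (y_pred == lab)))
        fn = int(np.sum((y_true == lab) & (y_pred != lab)))
        support = int(np.sum(y_true == lab))
        if tp + fp == 0:
            warnings.warn(f"precision undefined for {lab.to_string()}; reporting 0")
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        if support == 0:
            warnings.warn(f"recall undefined for {lab.to_string()}; reporting 0")
            recall = 0.0
        else:
            recall = tp / (tp + fn)
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        rows[lab.to_string()] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def label_mse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean squared difference of integer label codes."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.mean((y_true - y_pred) ** 2))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((_N_CLASSES, _N_CLASSES), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def _prepare(matrix: FeatureMatrix, selected: SelectedFeatureSet | None):
    names = tuple(selected.names) if selected is not None else tuple(
        c
        for c in matrix.frame.columns
        if c not in ("subject", "window_start_s", "label")
    )
    frame = matrix.frame
    X = frame[list(names)].to_numpy(dtype=float)
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        logger.info("evaluation: dropping %d incomplete rows", int((~keep).sum()))
    frame = frame[keep].reset_index(drop=True)
    y = np.array([BehaviorLabel.from_string(s).value for s in frame["label"]])
    return frame, y, names


def kfold_cv(
    matrix: FeatureMatrix,
    specs: list[ens.BaseClassifierSpec] | None = None,
    selected: SelectedFeatureSet | None = None,
    k: int = 10,
    seed: int = 0,
    vote_mode: str = "confidence",
) -> EvalReport:
    """Stratified k-fold CV with pooled out-of-fold predictions."""
    frame, y, names = _prepare(matrix, selected)
    if k > len(frame):
        raise ValueError(f"k={k} exceeds {len(frame)} usable rows")
    specs = specs if specs is not None else ens.default_specs(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true_all = np.empty_like(y)
    y_pred_all = np.empty_like(y)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = ens.fit(frame.iloc[tr], specs, names, vote_mode=vote_mode)
        preds = ens.predict_labels(model, frame.iloc[te])
        y_true_all[te] = y[te]
        y_pred_all[te] = preds
        acc = float(np.mean(preds == y[te]))
        per_fold.append({"fold": fold, "accuracy": acc, "n": int(len(te))})
    accs = [f["accuracy"] for f in per_fold]
    report = classification_report(y_true_all, y_pred_all)
    return EvalReport(
        scheme=f"kfold{k}",
        per_class=report,
        accuracy_mean=float(np.mean(accs)),
        accuracy_min=float(np.min(accs)),
        mse=label_mse(y_true_all, y_pred_all),
        confusion=_confusion(y_true_all, y_pred_all),
        per_fold=per_fold,
        note=(
            "k-fold folds are stratified by class; windows of one subject may "
            "appear in both train and test folds"
        ),
    )


def loo_subject_cv(
    matrix: FeatureMatrix,
    specs: list[ens.BaseClassifierSpec] | None = None,
    selected: SelectedFeatureSet | None = None,
    seed: int = 0,
    vote_mode: str = "confidence",
) -> EvalReport:
    """Leave-one-subject-out CV: one fold per subject."""
    frame, y, names = _prepare(matrix, selected)
    subjects = list(dict.fromkeys(frame["subject"]))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    specs = specs if specs is not None else ens.default_specs(seed)
    y_true_parts, y_pred_parts, per_fold = [], [], []
    subj_arr = frame["subject"].to_numpy()
    for fold, held_out in enumerate(subjects):
        te = np.flatnonzero(subj_arr == held_out)
        tr = np.flatnonzero(subj_arr != held_out)
        if len(set(y[te])) == 1:
            warnings.warn(f"subject {held_out} has a single class; fold kept")
        model = ens.fit(frame.iloc[tr], specs, names, vote_mode=vote_mode)
        preds = ens.predict_labels(model, frame.iloc[te])
        y_true_parts.append(y[te])
        y_pred_parts.append(preds)
        acc = float(np.mean(preds == y[te]))
        per_fold.append({"fold": fold, "subject": held_out, "accuracy": acc, "n": int(len(te))})
    y_true_all = np.concatenate(y_true_parts)
    y_pred_all = np.concatenate(y_pred_parts)
    accs = [f["accuracy"] for f in per_fold]
    return EvalReport(
        scheme="loo_subject",
        per_class=classification_report(y_true_all, y_pred_all),
        accuracy_mean=float(np.mean(accs)),
        accuracy_min=float(np.min(accs)),
        mse=label_mse(y_true_all, y_pred_all),
        confusion=_confusion(y_true_all, y_pred_all),
        per_fold=per_fold,
        note="one fold per held-out subject; mean accuracy over subjects, pooled MSE",
    )


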