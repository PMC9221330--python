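"""Confidence-weighted voting ensemble of four tree-based classifiers.

Each base classifier votes for its argmax class with weight equal to the
maximum class probability it assigns (its confidence); the ensemble returns
the class with the largest summed confidence.  With all confidences equal
this reduces to simple majority voting.  A full soft-voting variant
(summing whole probability vectors) is available via ``vote_mode='soft'``.

The XGBC member is backed by scikit-learn's histogram gradient boosting,
the same class of algorithm; see the README for the rationale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
)
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .model import BehaviorLabel
from .screening import SelectedFeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "BaseClassifierSpec",
    "ProbabilisticPrediction",
    "EnsembleModel",
    "ImportanceReport",
    "default_specs",
    "fit",
    "weighted_vote",
    "predict",
    "feature_importance",
]


@dataclass(frozen=True)
class BaseClassifierSpec:
    name: str
    hyperparameters: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def build(self):
        params = dict(self.hyperparameters)
        if self.name == "ETC":
            return ExtraTreesClassifier(random_state=self.seed, **{"n_estimators": 100, **params})
        if self.name == "DTC":
            return DecisionTreeClassifier(random_state=self.seed, **params)
        if self.name == "GBC":
            return GradientBoostingClassifier(random_state=self.seed, **{"n_estimators": 100, **params})
        if self.name == "XGBC":
            return HistGradientBoostingClassifier(random_state=self.seed, **{"max_iter": 100, **params})
        raise ValueError(f"unknown classifier name: {self.name}")


def default_specs(seed: int = 0) -> list[BaseClassifierSpec]:
    """The four-member default ensemble (m = 4)."""
    return [
        BaseClassifierSpec("ETC", seed=seed),
        BaseClassifierSpec("DTC", seed=seed),
        BaseClassifierSpec("GBC", seed=seed),
        BaseClassifierSpec("XGBC", seed=seed),
    ]


@dataclass
class ProbabilisticPrediction:
    """One classifier's per-class probability vector for one window."""

    probs: dict[int, float]
    predicted: int = field(init=False)
    confidence: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        # argmax with lowest-code tie-break
        self.predicted = min(
            self.probs, key=lambda lab: (-self.probs[lab], lab)
        )
        self.confidence = self.probs[self.predicted]


@dataclass
class EnsembleModel:
    members: dict[str, object]
    classes: tuple[int, ...]
    feature_names: tuple[str, ...]
    config_hash: str = ""
    vote_mode: str = "confidence"
    tie_count: int = 0


@dataclass
class ImportanceReport:
    per_member: dict[str, pd.Series]
    aggregate_rank: pd.Series


def fit(
    matrix: FeatureMatrix | pd.DataFrame,
    specs: list[BaseClassifierSpec] | None = None,
    selected: SelectedFeatureSet | None = None,
    vote_mode: str = "confidence",
) -> EnsembleModel:
    """Fit every base classifier independently on identical rows."""
    frame = matrix.frame if isinstance(matrix, FeatureMatrix) else matrix
    specs = specs if specs is not None else default_specs()
    if isinstance(selected, SelectedFeatureSet):
        names = tuple(selected.names)
    elif selected is not None:
        names = tuple(selected)
    else:
        names = tuple(
            c for c in frame.columns if c not in ("subject", "window_start_s", "label")
        )
    if len(frame) == 0:
        raise ValueError("empty matrix")
    X = frame[list(names)].to_numpy(dtype=float)
    y = np.array([BehaviorLabel.from_string(s).value for s in frame["label"]])
    keep = np.isfinite(X).all(axis=1)
    if not keep.all():
        logger.info("fit: dropping %d rows with missing features", int((~keep).sum()))
        X, y = X[keep], y[keep]
    classes = tuple(sorted(set(int(v) for v in y)))
    if len(classes) < 2:
        raise ValueError("degenerate labels: fewer than two classes")
    members = {}
    for spec in specs:
        clf = spec.build()
        clf.fit(X, y)
        members[spec.name] = clf
    logger.info("fitted ensemble of %d members on %d rows", len(members), len(y))
    return EnsembleModel(
        members=members,
        classes=classes,
        feature_names=names,
        vote_mode=vote_mode,
    )


def weighted_vote(
    predictions: list[ProbabilisticPrediction],
) -> tuple[int, dict[int, float]]:
    """Combine base predictions: g(L) = sum of confidences of the
    classifiers voting for L; argmax g wins, ties to the lowest label code."""
    if not predictions:
        raise ValueError("need at least one prediction")
    label_sets = {frozenset(p.probs) for p in predictions}
    if len(label_sets) != 1:
        raise ValueError("label mismatch between base predictions")
    labels = sorted(label_sets.pop())
    g = {lab: 0.0 for lab in labels}
    for p in predictions:
        g[p.predicted] += p.confidence
    best = max(g.values())
    winners = [lab for lab in labels if g[lab] == best]
    if len(winners) > 1:
        logger.info("weighted_vote tie between %s; lowest code wins", winners)
    return winners[0], g


def _soft_vote(
    predictions: list[ProbabilisticPrediction],
) -> tuple[int, dict[int, float]]:
    labels = sorted(predictions[0].probs)
    g = {lab: sum(p.probs[lab] for p in predictions) for lab in labels}
    best = max(g.values())
    return min(lab for lab in labels if g[lab] == best), g


def predict(
    model: EnsembleModel, rows: pd.DataFrame | FeatureMatrix
) -> list[dict]:
    """Per row: each member's probabilistic prediction, the vote scores g,
    and the ensemble label.  Full transparency for the evaluation stage."""
    frame = rows.frame if isinstance(rows, FeatureMatrix) else rows
    missing = [n for n in model.feature_names if n not in frame.columns]
    if missing:
        raise ValueError(f"schema mismatch: missing feature columns {missing}")
    X = frame[list(model.feature_names)].to_numpy(dtype=float)
    member_probs = {
        name: clf.predict_proba(X) for name, clf in model.members.items()
    }
    out: list[dict] = []
    for i in range(X.shape[0]):
        preds = {}
        for name, probs in member_probs.items():
            clf = model.members[name]
            p = {int(c): float(v) for c, v in zip(clf.classes_, probs[i])}
            # guard against tiny numeric drift off the simplex
            s = sum(p.values())
            p = {k: v / s for k, v in p.items()}
            preds[name] = ProbabilisticPrediction(p)
        plist = list(preds.values())
        if model.vote_mode == "soft":
            label, g = _soft_vote(plist)
        else:
            label, g = weighted_vote(plist)
        out.append({"label": label, "base": preds, "g": g})
    return out


def predict_labels(model: EnsembleModel, rows) -> np.ndarray:
    return np.array([p["label"] for p in predict(model, rows)])


def feature_importance(model: EnsembleModel) -> ImportanceReport:
    """Normalized per-member importances plus a mean-rank aggregate.

    Members that do not expose impurity importances (the histogram booster)
    are excluded with a log entry.
    """
    per_member: dict[str, pd.Series] = {}
    for name, clf in model.members.items():
        imp = getattr(clf, "feature_importances_", None)
        if imp is None:
            logger.info("feature_importance: %s exposes no importances, excluded", name)
            continue
        imp = np.asarray(imp, dtype=float)
        total = imp.sum()
        if total > 0:
            imp = imp / total
        per_member[name] = pd.Series(imp, index=list(model.feature_names))
    if not per_member:
        raise ValueError("no member exposes feature importances")
    ranks = pd.DataFrame(
        {name: s.rank(ascending=False) for name, s in per_member.items()}
    )
    aggregate = ranks.mean(axis=1).sort_values()
    return ImportanceReport(per_member=per_member, aggregate_rank=aggregate)
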