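"""Feature screening: inter-feature Pearson correlation, Kendall
feature-difficulty association, and the retained-feature selection step."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, FeatureMatrix
from .model import DifficultyTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationReport",
    "SelectedFeatureSet",
    "PAPER_FEATURE_SET",
    "pearson",
    "kendall_tau",
    "correlation_report",
    "difficulty_association",
    "per_subject_association",
    "mean_difficulty",
    "select_features",
]

#: the 19 features retained after importance-based screening
PAPER_FEATURE_SET: tuple[str, ...] = (
    "nn", "sdnn", "pnn50", "pnn20", "vlf", "lf", "hf",
    "resp_value", "resp_mean", "resp_std",
    "sc_value", "sc_mean", "sc_std",
    "emg_mean", "emg_std", "emg_rms", "iemg", "emg_mf", "emg_mpf",
)


@dataclass
class CorrelationReport:
    matrix: pd.DataFrame
    pairs_flagged: list[tuple[str, str, float]]


@dataclass
class SelectedFeatureSet:
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [n for n in self.names if n not in FEATURE_NAMES]
        if unknown:
            raise ValueError(f"unknown feature: {unknown}")

    def __len__(self) -> int:
        return len(self.names)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r = cov(x, y) / (sigma_x * sigma_y); NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.mean(xc**2))
    sy = np.sqrt(np.mean(yc**2))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.mean(xc * yc) / (sx * sy))


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected Kendall tau-b; NaN when either input is all tied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def correlation_report(
    matrix: FeatureMatrix, r_threshold: float = 0.9
) -> CorrelationReport:
    """Symmetric 28x28 Pearson matrix plus the |r| > threshold pairs."""
    df = matrix.features()
    n = len(FEATURE_NAMES)
    out = np.full((n, n), np.nan)
    cols = [df[name].to_numpy() for name in FEATURE_NAMES]
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            xi, yj = cols[i], cols[j]
            ok = np.isfinite(xi) & np.isfinite(yj)
            if ok.sum() >= 2:
                r = pearson(xi[ok], yj[ok])
            else:
                r = np.nan
            out[i, j] = out[j, i] = r
    mat = pd.DataFrame(out, index=list(FEATURE_NAMES), columns=list(FEATURE_NAMES))
    flagged = [
        (FEATURE_NAMES[i], FEATURE_NAMES[j], float(out[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(out[i, j]) and abs(out[i, j]) > r_threshold
    ]
    return CorrelationReport(matrix=mat, pairs_flagged=flagged)


def _window_difficulty(
    matrix: FeatureMatrix, table: DifficultyTable, source: str
) -> np.ndarray:
    """Difficulty value for each window row: the subject's own rating for
    the window's behavior, or the cohort mean rating for that behavior."""
    if source == "mean":
        means = table.behavior_means(decimals=10)
        return np.array([float(means[lab]) for lab in matrix.frame["label"]])
    return np.array(
        [
            float(table.rating(sub, lab))
            for sub, lab in zip(matrix.frame["subject"], matrix.frame["label"])
        ]
    )


def difficulty_association(
    matrix: FeatureMatrix,
    table: DifficultyTable,
    source: str = "own",
    tau_moderate: float = 0.1,
    tau_high: float = 0.3,
) -> pd.DataFrame:
    """Per-feature Kendall tau against window difficulty.

    Returns a frame indexed by feature with ``tau``, ``sign`` and a
    none/moderate/high ``band``.  Entirely-missing or constant features are
    excluded with a log entry.
    """
    difficulty = _window_difficulty(matrix, table, source)
    rows = {}
    for name in FEATURE_NAMES:
        x = matrix.frame[name].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 2 or np.all(x[ok] == x[ok][0]):
            logger.info("difficulty association: excluding %s (missing/constant)", name)
            continue
        tau = kendall_tau(x[ok], difficulty[ok])
        band = (
            "high" if abs(tau) > tau_high
            else "moderate" if abs(tau) > tau_moderate
            else "none"
        )
        rows[name] = {"tau": tau, "sign": int(np.sign(tau)), "band": band}
    return pd.DataFrame.from_dict(rows, orient="index")


def per_subject_association(
    matrix: FeatureMatrix, table: DifficultyTable, source: str = "mean"
) -> dict[str, pd.Series]:
    """Per-subject per-feature tau, for trend-recovery checks."""
    out: dict[str, pd.Series] = {}
    for subject, sub_frame in matrix.frame.groupby("subject"):
        sub_matrix = FeatureMatrix(sub_frame.reset_index(drop=True))
        assoc = difficulty_association(sub_matrix, table, source=source)
        out[str(subject)] = assoc["tau"]
    return out


def mean_difficulty(table: DifficultyTable) -> pd.Series:
    """Arithmetic mean rating per behavior, rounded to two decimals."""
    return table.behavior_means(decimals=2)


def select_features(
    matrix: FeatureMatrix,
    mode: str = "paper",
    r_threshold: float = 0.9,
    importance_rank: dict[str, float] | None = None,
) -> tuple[SelectedFeatureSet, FeatureMatrix]:
    """Reduce the matrix to a retained feature subset.

    ``mode='paper'`` keeps the published 19-feature set.  ``mode='threshold'``
    drops, from each |r| > ``r_threshold`` pair, the member with the worse
    importance rank, or the later one in canonical order when no ranks are
    given.
    """
    if mode == "paper":
        selected = SelectedFeatureSet(PAPER_FEATURE_SET)
    elif mode == "threshold":
        report = correlation_report(matrix, r_threshold)
        dropped: set[str] = set()
        for a, b, _r in report.pairs_flagged:
            if a in dropped or b in dropped:
                continue
            if importance_rank is not None:
                # higher rank value = more important
                victim = a if importance_rank.get(a, 0) < importance_rank.get(b, 0) else b
            else:
                victim = b if FEATURE_NAMES.index(b) > FEATURE_NAMES.index(a) else a
            dropped.add(victim)
        selected = SelectedFeatureSet(
            tuple(n for n in FEATURE_NAMES if n not in dropped)
        )
    else:
        raise ValueError("mode must be 'paper' or 'threshold'")
    keep_cols = ["subject", "window_start_s", *selected.names, "label"]
    reduced = matrix.frame[keep_cols].copy()
    logger.info(
        "selected %d of %d features (%s mode)", len(selected), len(FEATURE_NAMES), mode
    )
    return selected, reduced
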