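"""Core domain types shared by every pipeline stage.

All times are seconds from the start of the recording.  Label segments are
half-open intervals ``[start, end)`` so a boundary sample belongs to exactly
one behavior.
"""
from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChannelKind",
    "BehaviorLabel",
    "BEHAVIOR_NAMES",
    "ChannelRecording",
    "LabelTrack",
    "LabeledRecordingSet",
    "DifficultyTable",
    "PipelineConfig",
]


class ChannelKind(enum.Enum):
    """The five wearable modalities and their native sampling rates."""

    ECG = "ECG"
    GSR = "GSR"
    EMG = "EMG"
    RESP = "RESP"
    SKT = "SKT"

    @property
    def native_rate(self) -> float:
        """Canonical acquisition rate in Hz."""
        return _NATIVE_RATES[self]


_NATIVE_RATES: dict[ChannelKind, float] = {
    ChannelKind.ECG: 512.0,
    ChannelKind.GSR: 64.0,
    ChannelKind.EMG: 1024.0,
    ChannelKind.RESP: 64.0,
    ChannelKind.SKT: 32.0,
}


class BehaviorLabel(enum.IntEnum):
    """Six flight maneuvers; the integer codes are fixed pipeline-wide."""

    TAKEOFF = 0
    LEVEL_FLIGHT = 1
    TURN_AND_HOVER = 2
    ROLL = 3
    SOMERSAULT = 4
    STALL = 5

    @classmethod
    def from_string(cls, name: str) -> "BehaviorLabel":
        key = name.strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return cls[key.upper()]
        except KeyError:
            raise ValueError(f"unknown behavior: {name!r}") from None

    def to_string(self) -> str:
        return self.name.lower()


#: Serialization names in code order; files always carry these, never codes.
BEHAVIOR_NAMES: tuple[str, ...] = tuple(b.to_string() for b in BehaviorLabel)


@dataclass
class ChannelRecording:
    """A single physiological channel of one subject."""

    subject_id: str
    kind: ChannelKind
    rate: float
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChannelRecording):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.kind == other.kind
            and self.rate == other.rate
            and self.start_time == other.start_time
            and np.array_equal(self.samples, other.samples)
        )


@dataclass(frozen=True)
class LabelTrack:
    """Ordered, non-overlapping behavior segments on the recording clock."""

    segments: tuple[tuple[float, float, BehaviorLabel], ...]

    def __init__(self, segments: Iterable[tuple[float, float, BehaviorLabel]]):
        segs = tuple((float(s), float(e), BehaviorLabel(l)) for s, e, l in segments)
        for s, e, _ in segs:
            if not e > s:
                raise ValueError("invalid label track: empty or reversed segment")
        for (s0, e0, _), (s1, e1, _) in zip(segs, segs[1:]):
            if s1 < e0:
                raise ValueError("invalid label track: overlapping segments")
        object.__setattr__(self, "segments", segs)

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0][0], self.segments[-1][1]

    def label_at(self, t: float) -> BehaviorLabel | None:
        for s, e, lab in self.segments:
            if s <= t < e:
                return lab
        return None

    def majority_label(self, start: float, end: float) -> BehaviorLabel | None:
        """Behavior covering the largest share of ``[start, end)``.

        Returns ``None`` if no segment overlaps the window.  Ties go to the
        lower label code for determinism.
        """
        cover: dict[BehaviorLabel, float] = {}
        for s, e, lab in self.segments:
            ov = min(end, e) - max(start, s)
            if ov > 0:
                cover[lab] = cover.get(lab, 0.0) + ov
        if not cover:
            return None
        return max(sorted(cover), key=lambda lab: cover[lab])

    def coverage(self, start: float, end: float) -> float:
        """Fraction of ``[start, end)`` covered by any segment."""
        tot = sum(
            max(0.0, min(end, e) - max(start, s)) for s, e, _ in self.segments
        )
        return tot / (end - start)


@dataclass
class LabeledRecordingSet:
    """All five channels of one subject plus the behavior label track."""

    subject_id: str
    channels: dict[ChannelKind, ChannelRecording]
    label_track: LabelTrack

    def __post_init__(self) -> None:
        missing = [k for k in ChannelKind if k not in self.channels]
        if missing:
            raise ValueError(
                "incomplete modality set: missing "
                + ", ".join(k.value for k in missing)
            )
        lo, hi = self.label_track.span
        for kind, rec in self.channels.items():
            if rec.start_time > lo or rec.start_time + rec.duration < hi - 1e-9:
                raise ValueError(
                    f"channel {kind.value} does not cover the label track span"
                )

    @property
    def duration(self) -> float:
        return min(rec.duration for rec in self.channels.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledRecordingSet):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.label_track == other.label_track
            and set(self.channels) == set(other.channels)
            and all(self.channels[k] == other.channels[k] for k in self.channels)
        )


class DifficultyTable:
    """Per-subject, per-behavior subjective difficulty ratings (1-10)."""

    def __init__(self, ratings: pd.DataFrame):
        df = ratings.copy()
        df.columns = [BehaviorLabel.from_string(c).to_string() for c in df.columns]
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("ratings must be numeric")
        if np.any(vals < 1) or np.any(vals > 10):
            raise ValueError("ratings must lie in [1, 10]")
        if np.any(vals != np.round(vals)):
            raise ValueError("ratings must be integers")
        self.ratings = df.astype(int)

    @property
    def subjects(self) -> list[str]:
        return list(self.ratings.index)

    @property
    def behaviors(self) -> list[str]:
        return list(self.ratings.columns)

    def rating(self, subject: str, behavior: BehaviorLabel | str) -> int:
        name = (
            behavior.to_string()
            if isinstance(behavior, BehaviorLabel)
            else BehaviorLabel.from_string(behavior).to_string()
        )
        return int(self.ratings.loc[subject, name])

    def behavior_means(self, decimals: int = 2) -> pd.Series:
        """Arithmetic mean rating per behavior over all subjects."""
        return self.ratings.mean(axis=0).round(decimals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DifficultyTable):
            return NotImplemented
        return self.ratings.equals(other.ratings)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; defaults are the published values."""

    window_s: float = 30.0
    step_s: float = 10.0
    target_rate_hz: float = 2.0
    ectopic_threshold: float = 0.20
    impute_width: int = 11
    window_reject_fraction: float = 0.20
    reject_tile_s: float = 30.0
    random_seed: int = 0
    # HRV spectral estimation
    hrv_buffer_s: float = 300.0
    hrv_min_buffer_s: float = 120.0
    hrv_resample_hz: float = 4.0
    # RR physiologic gate after ectopic handling, ms
    rr_min_ms: float = 300.0
    rr_max_ms: float = 2000.0
    # Kendall association bands
    tau_moderate: float = 0.1
    tau_high: float = 0.3
    # feature screening
    r_threshold: float = 0.9
    # difficulty source for associations: each subject's own rating, or the
    # cohort mean per behavior
    difficulty_source: str = "own"  # "own" | "mean"
    # ensemble combiner: hard confidence-weighted votes, or full soft voting
    vote_mode: str = "confidence"  # "confidence" | "soft"

    def __post_init__(self) -> None:
        if not (self.window_s > self.step_s > 0):
            raise ValueError("window_s must exceed step_s, both positive")
        if self.impute_width % 2 != 1 or self.impute_width < 1:
            raise ValueError("impute_width must be odd and positive")
        for name in ("ectopic_threshold", "window_reject_fraction"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.target_rate_hz <= 0:
            raise ValueError("target_rate_hz must be positive")
        if self.difficulty_source not in ("own", "mean"):
            raise ValueError("difficulty_source must be 'own' or 'mean'")
        if self.vote_mode not in ("confidence", "soft"):
            raise ValueError("vote_mode must be 'confidence' or 'soft'")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            f.name: type(f.default)(mapping[f.name])
            for f in fields(cls)
            if f.name in mapping
        }
        return cls(**kwargs)
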