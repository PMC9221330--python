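"""Sliding-window multi-modal feature extraction (30 s window, 10 s step).

The 28 fused features, in canonical order: a 13-feature ECG block
(instantaneous value, HR, NN and the time/frequency HRV statistics), a
3-feature skin-conductance block, a 7-feature EMG block, a 4-feature
respiration block, and the instantaneous skin temperature.

Notes on conventions:

* ``*_value`` features are the 2 Hz downsampled stream sampled at the window
  end.
* EMG ``mean``/``std`` are computed on the rectified signal: the raw mean of
  a zero-mean (high-pass filtered) EMG is identically ~0 and it is the
  rectified mean that moves with muscle activation and tracks iEMG.
* Spectral HRV bands use the standard ULF/VLF/LF/HF edges on a 4 Hz
  resampled tachogram over a rolling 5-min buffer ending at the window;
  windows with less than 2 min of buffered beats get missing ULF/VLF.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .model import (
    BehaviorLabel,
    ChannelKind,
    LabeledRecordingSet,
    PipelineConfig,
)
from .preprocess import BeatSeries, CleanRecordingSet, clean_recording_set

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "CORE_FEATURES",
    "FeatureWindow",
    "FeatureMatrix",
    "make_windows",
    "stat_features",
    "hrv_time_features",
    "hrv_freq_features",
    "emg_features",
    "resp_features",
    "fuse",
    "extract_features",
]

FEATURE_NAMES: tuple[str, ...] = (
    # ECG block (13)
    "ecg_value", "hr", "nn", "sdnn", "sdsd", "rmssd", "pnn50", "pnn20",
    "ulf", "vlf", "lf", "hf", "lf_hf",
    # GSR block (3)
    "sc_value", "sc_mean", "sc_std",
    # EMG block (7)
    "emg_value", "emg_mean", "emg_std", "emg_rms", "iemg", "emg_mf", "emg_mpf",
    # RESP block (4)
    "resp_value", "resp_mean", "resp_std", "resp_freq",
    # SKT block (1)
    "skt_value",
)

#: features whose absence flags the whole row (ULF/VLF are buffer-limited
#: early in a recording and excluded from the core set on purpose)
CORE_FEATURES: tuple[str, ...] = tuple(
    n for n in FEATURE_NAMES if n not in ()
)

# HRV band edges, Hz
ULF_BAND = (0.0, 0.003)
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

RESP_FREQ_BAND = (0.05, 1.0)


@dataclass
class FeatureWindow:
    subject_id: str
    window_start_s: float
    values: dict[str, float]
    label: BehaviorLabel
    missing_mask: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        self.missing_mask = {
            n: not np.isfinite(self.values.get(n, np.nan)) for n in FEATURE_NAMES
        }


@dataclass
class FeatureMatrix:
    """Tabular view of the fused windows.

    ``frame`` columns: ``subject``, ``window_start_s``, the 28 canonical
    features, ``label`` (behavior name).
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        dup = self.frame.duplicated(subset=["subject", "window_start_s"])
        if dup.any():
            raise ValueError("duplicated (subject, window_start) keys")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def features(self) -> pd.DataFrame:
        return self.frame[list(FEATURE_NAMES)]

    def labels(self) -> np.ndarray:
        return np.array(
            [BehaviorLabel.from_string(s).value for s in self.frame["label"]]
        )

    def complete_rows(self, names: tuple[str, ...] | list[str] = FEATURE_NAMES) -> "FeatureMatrix":
        keep = self.frame[list(names)].notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d incomplete rows of %d", dropped, len(self.frame))
        return FeatureMatrix(self.frame[keep].reset_index(drop=True), self.provenance)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        a, b = self.frame, other.frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind in "fc":
                ok = np.allclose(a[c], b[c], rtol=1e-12, atol=0, equal_nan=True)
            else:
                ok = (a[c] == b[c]).all()
            if not ok:
                return False
        return True


def make_windows(
    rset: LabeledRecordingSet | CleanRecordingSet,
    window_s: float = 30.0,
    step_s: float = 10.0,
    rejected: list[tuple[float, float]] | None = None,
) -> list[tuple[float, BehaviorLabel]]:
    """Sliding-window grid with majority labels.

    Windows overlapping a rejected tile or a label-track gap are dropped.
    """
    track = rset.label_track
    duration = (
        rset.duration
        if isinstance(rset, LabeledRecordingSet)
        else min(ch.recording.duration for ch in rset.channels.values())
    )
    if rejected is None:
        rejected = (
            rset.rejected_windows if isinstance(rset, CleanRecordingSet) else []
        )
    out: list[tuple[float, BehaviorLabel]] = []
    start = 0.0
    while start + window_s <= duration + 1e-9:
        end = start + window_s
        if any(s < end and start < e for s, e in rejected):
            start += step_s
            continue
        if track.coverage(start, end) < 1.0 - 1e-9:
            start += step_s
            continue
        label = track.majority_label(start, end)
        if label is not None:
            out.append((start, label))
        start += step_s
    return out


def stat_features(x: np.ndarray) -> tuple[float, float, float]:
    """Mean, population SD, and RMS by the direct formulas."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return (math.nan, math.nan, math.nan)
    mean = float(np.sum(x) / x.size)
    std = float(np.sqrt(np.sum((x - mean) ** 2) / x.size))
    rms = float(np.sqrt(np.sum(x**2) / x.size))
    return mean, std, rms


def hrv_time_features(beats: BeatSeries) -> dict[str, float]:
    """NN/HR and the time-domain HRV set from the gated RR intervals."""
    rr = beats.rr_intervals_ms[beats.rr_valid]
    nan = {k: math.nan for k in ("nn", "hr", "sdnn", "rmssd", "sdsd", "pnn50", "pnn20")}
    if rr.size < 2:
        return nan
    nn = float(np.mean(rr))
    d = np.diff(rr)
    out = {
        "nn": nn,
        "hr": 60000.0 / nn,
        "sdnn": float(np.std(rr)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
        "sdsd": float(np.std(d)),
        "pnn50": float(100.0 * np.mean(np.abs(d) > 50.0)),
        "pnn20": float(100.0 * np.mean(np.abs(d) > 20.0)),
    }
    return out


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi], with interpolation at
    the band edges so narrow bands below the grid resolution still integrate."""
    if freqs.size < 2:
        return math.nan
    grid = np.linspace(lo, hi, 200)
    p = np.interp(grid, freqs, psd, left=0.0, right=0.0)
    return float(np.trapezoid(p, grid))


def hrv_freq_features(
    beats: BeatSeries,
    window_end_s: float,
    buffer_s: float = 300.0,
    min_buffer_s: float = 120.0,
    resample_hz: float = 4.0,
    t_floor: float = 0.0,
) -> dict[str, float]:
    """Band powers of the RR tachogram over a rolling buffer ending at the
    window.  ULF/VLF require ``min_buffer_s`` of beats; LF/HF are estimated
    whenever at least 60 s of tachogram is available.

    ``t_floor`` truncates the buffer (the fusion stage passes the current
    behavior segment's start, so spectra never mix behaviors)."""
    out = {k: math.nan for k in ("ulf", "vlf", "lf", "hf", "lf_hf")}
    t0 = max(0.0, t_floor, window_end_s - buffer_s)
    m = (beats.r_peak_times_s >= t0) & (beats.r_peak_times_s <= window_end_s)
    times = beats.r_peak_times_s[m]
    if times.size < 4:
        return out
    rr = np.diff(times) * 1000.0
    mid = (times[:-1] + times[1:]) / 2.0
    span = mid[-1] - mid[0]
    if span < 60.0:
        return out
    tt = np.arange(mid[0], mid[-1], 1.0 / resample_hz)
    tach = np.interp(tt, mid, rr)
    tach = tach - np.mean(tach)
    nperseg = min(tach.size, int(120.0 * resample_hz))
    freqs, psd = sps.welch(
        tach, fs=resample_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    lf = _band_power(freqs, psd, *LF_BAND)
    hf = _band_power(freqs, psd, *HF_BAND)
    out["lf"] = lf
    out["hf"] = hf
    out["lf_hf"] = lf / hf if hf > 0 else math.nan
    if span >= min_buffer_s:
        out["ulf"] = _band_power(freqs, psd, *ULF_BAND)
        out["vlf"] = _band_power(freqs, psd, *VLF_BAND)
    return out


def emg_features(x: np.ndarray, rate: float) -> dict[str, float]:
    """Rectified-signal statistics plus spectral median/mean frequency."""
    x = np.asarray(x, dtype=float)
    nan = {k: math.nan for k in ("emg_mean", "emg_std", "emg_rms", "iemg", "emg_mf", "emg_mpf")}
    if x.size == 0:
        return nan
    rect = np.abs(x)
    mean, std, _ = stat_features(rect)
    _, _, rms = stat_features(x)
    iemg = float(np.sum(rect) / rate)
    out = {"emg_mean": mean, "emg_std": std, "emg_rms": rms, "iemg": iemg}
    nperseg = min(x.size, int(4.0 * rate))
    freqs, psd = sps.welch(
        x, fs=rate, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    total = np.trapezoid(psd, freqs)
    if total <= 0:
        out["emg_mf"] = math.nan
        out["emg_mpf"] = math.nan
        return out
    cum = np.concatenate([[0.0], np.cumsum((psd[1:] + psd[:-1]) / 2.0 * np.diff(freqs))])
    out["emg_mf"] = float(np.interp(total / 2.0, cum, freqs))
    out["emg_mpf"] = float(np.trapezoid(freqs * psd, freqs) / total)
    return out


def resp_features(x: np.ndarray, rate: float) -> dict[str, float]:
    """Window statistics plus the dominant breathing frequency.

    The spectral peak is refined by parabolic interpolation; a peak less
    than five times the in-band median power is treated as noise."""
    x = np.asarray(x, dtype=float)
    out = {"resp_value": math.nan, "resp_mean": math.nan, "resp_std": math.nan, "resp_freq": math.nan}
    if x.size == 0:
        return out
    mean, std, _ = stat_features(x)
    out["resp_value"] = float(x[-1])
    out["resp_mean"] = mean
    out["resp_std"] = std
    freqs, psd = sps.periodogram(x - np.mean(x), fs=rate, window="hann")
    band = (freqs >= RESP_FREQ_BAND[0]) & (freqs <= RESP_FREQ_BAND[1])
    if band.sum() < 3:
        return out
    fb, pb = freqs[band], psd[band]
    k = int(np.argmax(pb))
    floor = float(np.median(pb))
    if pb[k] <= 5.0 * floor or pb[k] <= 0:
        return out
    if 0 < k < pb.size - 1 and pb[k - 1] > 0 and pb[k + 1] > 0:
        # quadratic interpolation of log power around the peak bin
        la, lb, lc = np.log(pb[k - 1]), np.log(pb[k]), np.log(pb[k + 1])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = fb[1] - fb[0]
    out["resp_freq"] = float(fb[k] + delta * df)
    return out


def _value_at(twohz: np.ndarray, end_s: float, target_rate: float) -> float:
    idx = int(round(end_s * target_rate)) - 1
    if idx < 0 or idx >= twohz.size:
        return math.nan
    return float(twohz[idx])


def fuse(clean: CleanRecordingSet, cfg: PipelineConfig | None = None) -> FeatureMatrix:
    """Assemble the 28 canonical features on the common window grid.

    Rows with missing core features are flagged via NaN, never dropped here.
    """
    cfg = cfg or clean.config or PipelineConfig()
    windows = make_windows(clean, cfg.window_s, cfg.step_s)
    ecg2 = clean.twohz[ChannelKind.ECG]
    gsr2 = clean.twohz[ChannelKind.GSR]
    emg2 = clean.twohz[ChannelKind.EMG]
    skt2 = clean.twohz[ChannelKind.SKT]
    gsr = clean.channels[ChannelKind.GSR]
    emg = clean.channels[ChannelKind.EMG]
    resp = clean.channels[ChannelKind.RESP]
    rows = []
    for start, label in windows:
        end = start + cfg.window_s
        vals: dict[str, float] = {}
        vals["ecg_value"] = _value_at(ecg2, end, cfg.target_rate_hz)
        vals["sc_value"] = _value_at(gsr2, end, cfg.target_rate_hz)
        vals["emg_value"] = _value_at(emg2, end, cfg.target_rate_hz)
        vals["skt_value"] = _value_at(skt2, end, cfg.target_rate_hz)
        vals.update(hrv_time_features(clean.beats.in_window(start, end)))
        seg_start = 0.0
        for s, e, _lab in clean.label_track.segments:
            if s < end <= e + 1e-9:
                seg_start = s
                break
        vals.update(
            hrv_freq_features(
                clean.beats,
                end,
                buffer_s=cfg.hrv_buffer_s,
                min_buffer_s=cfg.hrv_min_buffer_s,
                resample_hz=cfg.hrv_resample_hz,
                t_floor=seg_start,
            )
        )
        g = gsr.samples[int(start * gsr.rate) : int(end * gsr.rate)]
        sc_mean, sc_std, _ = stat_features(g)
        vals["sc_mean"] = sc_mean
        vals["sc_std"] = sc_std
        e = emg.samples[int(start * emg.rate) : int(end * emg.rate)]
        vals.update(emg_features(e, emg.rate))
        r = resp.samples[int(start * resp.rate) : int(end * resp.rate)]
        rf = resp_features(r, resp.rate)
        vals["resp_mean"] = rf["resp_mean"]
        vals["resp_std"] = rf["resp_std"]
        vals["resp_freq"] = rf["resp_freq"]
        vals["resp_value"] = _value_at(clean.twohz[ChannelKind.RESP], end, cfg.target_rate_hz)
        rows.append(
            {
                "subject": clean.subject_id,
                "window_start_s": start,
                **{n: vals.get(n, math.nan) for n in FEATURE_NAMES},
                "label": label.to_string(),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["subject", "window_start_s", *FEATURE_NAMES, "label"]
    )
    logger.info(
        "%s: %d windows fused (%d with missing features)",
        clean.subject_id,
        len(frame),
        int(frame[list(FEATURE_NAMES)].isna().any(axis=1).sum()) if len(frame) else 0,
    )
    return FeatureMatrix(frame, provenance=cfg.config_hash())


def extract_features(
    rset: LabeledRecordingSet, cfg: PipelineConfig | None = None
) -> FeatureMatrix:
    """Convenience: clean all channels then fuse."""
    cfg = cfg or PipelineConfig()
    return fuse(clean_recording_set(rset, cfg), cfg)
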