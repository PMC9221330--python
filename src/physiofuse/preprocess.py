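"""Signal cleaning: normalization, ectopic/missing handling, filtering,
beat detection, and downsampling to the common 2 Hz clock.

Fixed stage order (logged): ectopic/missing flagging -> 30-s tile rejection
-> z-score normalization -> imputation -> filter bank -> beat detection /
native-rate spectral work -> 2 Hz downsampling.

The relative-change ("20 %") ectopic rule is evaluated on *raw* sample
values: a percent change is only meaningful for positive-baseline, slowly
varying series, so the amplitude rule is applied to GSR and SKT samples and
to the derived inter-beat-interval series, while zero-mean oscillatory
channels (ECG, EMG, RESP) get non-finite flagging only.  The rule itself is
implemented exactly as stated and unit-testable on any sequence.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from . import _wavelet
from .model import ChannelKind, ChannelRecording, LabeledRecordingSet, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "CleanChannel",
    "CleanRecordingSet",
    "BeatSeries",
    "zscore_normalize",
    "detect_ectopic",
    "reject_windows",
    "impute",
    "filter_channel",
    "detect_r_peaks",
    "downsample",
    "clean_channel",
    "clean_recording_set",
]

#: channels on which the relative-change ectopic rule is physically meaningful
AMPLITUDE_ECTOPIC_KINDS = frozenset({ChannelKind.GSR, ChannelKind.SKT})

# Table of per-channel filter-bank settings: (denoise method, high-pass Hz,
# band-stop Hz, low-pass Hz).  ``None`` means the stage is absent; the SKT
# high-pass is configured but marked unreliable (it would erase the signal)
# and is skipped with a log entry.
_FILTER_BANK: dict[ChannelKind, dict] = {
    ChannelKind.ECG: {"denoise": "wavelet", "hp": 1.0, "notch": 50.0, "lp": 40.0},
    ChannelKind.GSR: {"denoise": "gaussian", "hp": None, "notch": 50.0, "lp": 5.0},
    ChannelKind.EMG: {"denoise": "wavelet", "hp": 5.0, "notch": 50.0, "lp": 500.0},
    ChannelKind.RESP: {"denoise": "wavelet", "hp": None, "notch": 50.0, "lp": 20.0},
    ChannelKind.SKT: {
        "denoise": "sliding",
        "hp": 5.0,
        "hp_unreliable": True,
        "notch": 50.0,
        "lp": 200.0,
    },
}

GSR_GAUSS_SIGMA_S = 0.25
SKT_SLIDING_S = 1.0
NOTCH_Q = 30.0


@dataclass
class BeatSeries:
    """Detected R-peak times and the derived inter-beat intervals."""

    r_peak_times_s: np.ndarray
    rr_intervals_ms: np.ndarray = field(init=False)
    rr_valid: np.ndarray = field(init=False)
    rr_min_ms: float = 300.0
    rr_max_ms: float = 2000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.r_peak_times_s, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("peak times must be strictly increasing")
        self.r_peak_times_s = t
        self.rr_intervals_ms = np.diff(t) * 1000.0
        self.rr_valid = (self.rr_intervals_ms >= self.rr_min_ms) & (
            self.rr_intervals_ms <= self.rr_max_ms
        )

    def in_window(self, start_s: float, end_s: float) -> "BeatSeries":
        m = (self.r_peak_times_s >= start_s) & (self.r_peak_times_s < end_s)
        return BeatSeries(self.r_peak_times_s[m], rr_min_ms=self.rr_min_ms, rr_max_ms=self.rr_max_ms)


@dataclass
class CleanChannel:
    """A preprocessed channel plus its cleaning provenance."""

    recording: ChannelRecording
    rejected_windows: list[tuple[float, float]]
    imputed_count: int
    filter_log: list[str]

    @property
    def kind(self) -> ChannelKind:
        return self.recording.kind

    @property
    def rate(self) -> float:
        return self.recording.rate

    @property
    def samples(self) -> np.ndarray:
        return self.recording.samples


@dataclass
class CleanRecordingSet:
    """All cleaned channels of one subject on a common clock."""

    subject_id: str
    channels: dict[ChannelKind, CleanChannel]
    beats: BeatSeries
    twohz: dict[ChannelKind, np.ndarray]
    label_track: object
    config: PipelineConfig

    @property
    def rejected_windows(self) -> list[tuple[float, float]]:
        out: set[tuple[float, float]] = set()
        for ch in self.channels.values():
            out.update(ch.rejected_windows)
        return sorted(out)


def zscore_normalize(x: np.ndarray) -> np.ndarray:
    """Standardize to zero mean, unit population SD."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    sd = float(np.std(x))
    if sd == 0.0:
        raise ValueError("constant signal")
    return (x - np.mean(x)) / sd


def detect_ectopic(
    x: np.ndarray, threshold: float = 0.20, max_run: int | None = 8
) -> np.ndarray:
    """Flag samples deviating more than ``threshold`` from the last accepted one.

    The reference is the previous *accepted* (unflagged, finite) sample, so a
    single spike does not cascade flags.  Non-finite samples are flagged as
    missing.  A zero reference makes the ratio undefined and the point is
    flagged.  Strict ``>`` at the boundary.

    A frozen reference would flag *everything* after a genuine level step, so
    after ``max_run`` consecutive amplitude flags the current sample is
    accepted as the new reference (pass ``max_run=None`` for the literal
    frozen-reference rule).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    mask = np.zeros(x.size, dtype=bool)
    ref = math.nan
    run = 0
    for i in range(x.size):
        v = x[i]
        if not math.isfinite(v):
            mask[i] = True
            continue
        if not math.isfinite(ref):  # first finite sample is accepted
            ref = v
            run = 0
            continue
        if max_run is not None and run >= max_run:
            ref = v  # re-anchor: the deviation is a sustained level change
            run = 0
            continue
        if ref == 0.0:
            mask[i] = True
            run += 1
            continue
        if abs(v - ref) / abs(ref) > threshold:
            mask[i] = True
            run += 1
        else:
            ref = v
            run = 0
    return mask


def reject_windows(
    x: np.ndarray,
    mask: np.ndarray,
    window_s: float = 30.0,
    reject_fraction: float = 0.20,
    rate: float = 1.0,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Remove 30-s tiles (anchored at t=0) with too many flagged samples.

    A tile is removed iff flagged/samples > ``reject_fraction`` (strict).
    Removed tiles are masked to NaN in the returned copy and listed as
    ``(start_s, end_s)``; downstream windows overlapping them are dropped.
    """
    x = np.asarray(x, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    tile = int(round(window_s * rate))
    rejected: list[tuple[float, float]] = []
    for start in range(0, x.size, tile):
        stop = min(start + tile, x.size)
        frac = mask[start:stop].mean()
        if frac > reject_fraction:
            x[start:stop] = np.nan
            rejected.append((start / rate, stop / rate))
    return x, rejected


def impute(x: np.ndarray, mask: np.ndarray, w: int = 11) -> np.ndarray:
    """Replace flagged points by the mean of the centered ``w``-wide
    neighborhood, excluding flagged neighbors; boundaries shrink the window;
    an all-flagged neighborhood falls back to the nearest unflagged value."""
    if w % 2 != 1 or w < 1:
        raise ValueError("w must be odd and positive")
    x = np.asarray(x, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return x
    good = ~mask
    vals = np.where(good, np.nan_to_num(x, nan=0.0), 0.0)
    kernel = np.ones(w)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(good.astype(float), kernel, mode="same")
    flagged = np.flatnonzero(mask)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums[flagged] / counts[flagged]
    x[flagged] = means
    # empty neighborhoods: nearest unflagged value
    bad = flagged[counts[flagged] == 0]
    if bad.size:
        good_idx = np.flatnonzero(good)
        if good_idx.size == 0:
            raise ValueError("cannot impute: all samples flagged")
        pos = np.searchsorted(good_idx, bad)
        pos_lo = np.clip(pos - 1, 0, good_idx.size - 1)
        pos_hi = np.clip(pos, 0, good_idx.size - 1)
        lo, hi = good_idx[pos_lo], good_idx[pos_hi]
        nearest = np.where(np.abs(bad - lo) <= np.abs(hi - bad), lo, hi)
        x[bad] = x[nearest]
    return x


def _nyquist_ok(cutoff: float, rate: float) -> bool:
    return cutoff < rate / 2.0


def filter_channel(
    x: np.ndarray, kind: ChannelKind, rate: float
) -> tuple[np.ndarray, list[str]]:
    """Per-channel filter bank: denoise, high-pass, 50 Hz notch, low-pass.

    Any stage whose cutoff meets or exceeds Nyquist is skipped and logged.
    Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    bank = _FILTER_BANK[kind]
    log: list[str] = []

    method = bank["denoise"]
    if method == "wavelet":
        depth = int(math.floor(math.log2(rate / 8.0)))
        x = _wavelet.denoise(x, depth)
        log.append(f"denoise:wavelet(db4,depth={depth})")
    elif method == "gaussian":
        x = gaussian_filter1d(x, sigma=GSR_GAUSS_SIGMA_S * rate)
        log.append(f"denoise:gaussian(sigma={GSR_GAUSS_SIGMA_S}s)")
    elif method == "sliding":
        x = uniform_filter1d(x, size=max(int(SKT_SLIDING_S * rate), 1))
        log.append(f"denoise:sliding({SKT_SLIDING_S}s)")

    hp = bank.get("hp")
    if hp is not None:
        if bank.get("hp_unreliable"):
            log.append(f"highpass:{hp}Hz skipped (unreliable table row)")
        elif not _nyquist_ok(hp, rate):
            log.append(f"highpass:{hp}Hz skipped (>= Nyquist {rate / 2:g})")
        else:
            sos = sps.butter(4, hp, btype="highpass", fs=rate, output="sos")
            x = sps.sosfiltfilt(sos, x)
            log.append(f"highpass:{hp}Hz")

    notch = bank.get("notch")
    if notch is not None:
        if not _nyquist_ok(notch, rate):
            log.append(f"bandstop:{notch}Hz skipped (>= Nyquist {rate / 2:g})")
        else:
            b, a = sps.iirnotch(notch, NOTCH_Q, fs=rate)
            x = sps.filtfilt(b, a, x)
            log.append(f"bandstop:{notch}Hz")

    lp = bank.get("lp")
    if lp is not None:
        if not _nyquist_ok(lp, rate):
            log.append(f"lowpass:{lp}Hz skipped (>= Nyquist {rate / 2:g})")
        else:
            sos = sps.butter(4, lp, btype="lowpass", fs=rate, output="sos")
            x = sps.sosfiltfilt(sos, x)
            log.append(f"lowpass:{lp}Hz")

    return x, log


def detect_r_peaks(
    x: np.ndarray,
    rate: float,
    rr_min_ms: float = 300.0,
    rr_max_ms: float = 2000.0,
) -> BeatSeries:
    """Derivative-square-integrate QRS detector with adaptive threshold."""
    x = np.asarray(x, dtype=float)
    if x.size < int(rate):
        return BeatSeries(np.empty(0), rr_min_ms=rr_min_ms, rr_max_ms=rr_max_ms)
    sos = sps.butter(3, [5.0, min(18.0, 0.45 * rate)], btype="bandpass", fs=rate, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    integ = uniform_filter1d(deriv**2, size=max(int(0.150 * rate), 1))
    refractory = int(0.25 * rate)
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        return BeatSeries(np.empty(0), rr_min_ms=rr_min_ms, rr_max_ms=rr_max_ms)
    heights = integ[cand]
    thr = 0.20 * np.percentile(heights, 90)
    cand = cand[heights > thr]
    # refine each detection to the local maximum of the band-passed signal
    half = int(0.08 * rate)
    peaks: list[int] = []
    for c in cand:
        lo, hi = max(c - half, 0), min(c + half + 1, x.size)
        p = lo + int(np.argmax(bp[lo:hi]))
        if not peaks or p - peaks[-1] >= refractory:
            peaks.append(p)
    times = np.asarray(peaks, dtype=float) / rate
    return BeatSeries(times, rr_min_ms=rr_min_ms, rr_max_ms=rr_max_ms)


def downsample(x: np.ndarray, rate: float, target_rate_hz: float = 2.0) -> np.ndarray:
    """Bin means on the target clock: output sample i is the mean of the
    source samples in ``[i, i+1) / target_rate_hz``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    n_out = int(math.floor(x.size / rate * target_rate_hz))
    edges = np.ceil(np.arange(n_out + 1) * rate / target_rate_hz).astype(int)
    out = np.empty(n_out)
    for i in range(n_out):
        out[i] = np.mean(x[edges[i] : edges[i + 1]])
    return out


def clean_channel(rec: ChannelRecording, cfg: PipelineConfig | None = None) -> CleanChannel:
    """Run the full per-channel cleaning chain; see the module docstring."""
    cfg = cfg or PipelineConfig()
    raw = rec.samples
    if rec.kind in AMPLITUDE_ECTOPIC_KINDS:
        flags = detect_ectopic(raw, cfg.ectopic_threshold)
    else:
        flags = ~np.isfinite(raw)
    _, rejected = reject_windows(
        raw, flags, cfg.reject_tile_s, cfg.window_reject_fraction, rec.rate
    )
    finite_ok = np.isfinite(raw) & ~flags
    if finite_ok.sum() < 2:
        raise ValueError("constant signal" if raw.size else "empty channel")
    mu = float(np.mean(raw[finite_ok]))
    sd = float(np.std(raw[finite_ok]))
    if sd == 0.0:
        raise ValueError("constant signal")
    z = (raw - mu) / sd
    z = impute(z, flags, cfg.impute_width)
    in_rejected = np.zeros(raw.size, dtype=bool)
    for s, e in rejected:
        in_rejected[int(s * rec.rate) : int(e * rec.rate)] = True
    imputed_count = int((flags & ~in_rejected).sum())
    y, flog = filter_channel(z, rec.kind, rec.rate)
    logger.info(
        "%s %s: %d samples, %d flagged, %d imputed, %d tiles rejected",
        rec.subject_id,
        rec.kind.value,
        raw.size,
        int(flags.sum()),
        imputed_count,
        len(rejected),
    )
    return CleanChannel(
        recording=ChannelRecording(
            rec.subject_id, rec.kind, rec.rate, y, rec.start_time
        ),
        rejected_windows=rejected,
        imputed_count=imputed_count,
        filter_log=flog,
    )


def clean_recording_set(
    rset: LabeledRecordingSet, cfg: PipelineConfig | None = None
) -> CleanRecordingSet:
    """Clean all five channels, detect beats, and derive the 2 Hz streams."""
    cfg = cfg or PipelineConfig()
    channels = {k: clean_channel(rec, cfg) for k, rec in rset.channels.items()}
    ecg = channels[ChannelKind.ECG]
    beats = detect_r_peaks(
        ecg.samples, ecg.rate, rr_min_ms=cfg.rr_min_ms, rr_max_ms=cfg.rr_max_ms
    )
    # the 20% ectopic rule on the derived RR series (ectopic beats), on top
    # of the physiologic gate applied by BeatSeries
    if beats.rr_intervals_ms.size:
        beats.rr_valid &= ~detect_ectopic(beats.rr_intervals_ms, cfg.ectopic_threshold)
    twohz = {
        k: downsample(ch.samples, ch.rate, cfg.target_rate_hz)
        for k, ch in channels.items()
    }
    logger.info(
        "%s: %d beats detected, %d valid RR",
        rset.subject_id,
        beats.r_peak_times_s.size,
        int(beats.rr_valid.sum()),
    )
    return CleanRecordingSet(
        subject_id=rset.subject_id,
        channels=channels,
        beats=beats,
        twohz=twohz,
        label_track=rset.label_track,
        config=cfg,
    )
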