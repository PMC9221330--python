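"""Synthetic labeled multi-channel biosignal generator.

The study's recordings are private, so this module fabricates cohorts whose
feature-level statistics carry the same difficulty-dependent structure the
analysis stages are meant to recover:

* mean inter-beat interval, slow (ultra-low-frequency) RR variability,
  LF/HF balance, and EMG activation all *decrease* with behavior difficulty;
* respiration rate and tonic skin conductance *increase* with difficulty.

Effect magnitudes are free design parameters chosen so the trends are
detectable at desk scale; only their directions are constrained.  Generation
is fully deterministic given a seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import load_difficulty_fixture
from .model import (
    BehaviorLabel,
    ChannelKind,
    ChannelRecording,
    LabeledRecordingSet,
    LabelTrack,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviorProfile",
    "SimPlan",
    "default_profiles",
    "default_schedule",
    "draw_rr_intervals",
    "simulate_ecg",
    "simulate_gsr",
    "simulate_emg",
    "simulate_resp",
    "simulate_skt",
    "simulate_recording_set",
    "simulate_cohort",
]

# frequency of the slow RR modulator driving ULF-band power (period 400 s)
ULF_MOD_HZ = 0.0025
# frequency of the LF-band RR modulator
LF_MOD_HZ = 0.10
# declared EMG noise floor (RMS of the activation-independent component)
EMG_NOISE_FLOOR = 0.02
# amplitude of a fully-activated EMG burst component (RMS)
EMG_FULL_SCALE = 1.0
# single skin-conductance response: amplitude scale (uS) and decay (s)
SCR_AMP_US = 0.3
SCR_DECAY_S = 4.0
SCR_RISE_S = 0.8
RESP_AMP = 1.0
RESP_OFFSET = 0.5


@dataclass(frozen=True)
class BehaviorProfile:
    """Generator-side causes of one behavior's physiological signature."""

    behavior: BehaviorLabel
    difficulty: float
    mean_rr_ms: float
    rr_sd_ms: float
    resp_rate_hz: float
    scl_level_uS: float
    scr_rate_per_min: float
    emg_activation: float
    skt_base_C: float = 33.2
    # narrowband RR modulator amplitudes, as fractions of rr_sd_ms, so a
    # zero-variance profile is exactly flat
    rr_ulf_frac: float = 0.6
    rr_lf_frac: float = 0.4
    rr_hf_frac: float = 0.25
    rr_white_frac: float = 0.08
    # additive measurement-noise SDs per channel (signal units)
    ecg_noise: float = 0.004
    gsr_noise_uS: float = 0.01
    resp_noise: float = 0.01
    skt_noise_C: float = 0.002

    def __post_init__(self) -> None:
        if not (400.0 <= self.mean_rr_ms <= 1500.0):
            raise ValueError("mean_rr_ms must lie in [400, 1500]")
        if not (0.1 <= self.resp_rate_hz <= 1.0):
            raise ValueError("resp_rate_hz must lie in [0.1, 1.0]")
        if not (0.0 <= self.emg_activation <= 1.0):
            raise ValueError("emg_activation must lie in [0, 1]")


@dataclass(frozen=True)
class SimPlan:
    """A reproducible cohort recipe."""

    subjects: int
    schedule: tuple[tuple[BehaviorLabel, float], ...]
    profiles: dict[BehaviorLabel, BehaviorProfile]
    seed: int = 0
    window_s: float = 30.0
    #: per-subject multiplicative log-normal jitter SD applied once per
    #: subject to each jittered profile parameter (individual differences)
    jitter_sd: float = 0.05
    #: rate of impulse/NaN artifacts injected into GSR/SKT, per minute;
    #: exists solely to exercise ectopic handling
    artifact_rate_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.subjects < 0:
            raise ValueError("subjects must be non-negative")
        for behavior, duration in self.schedule:
            if duration < 3 * self.window_s:
                raise ValueError(
                    f"segment too short: {behavior.to_string()} "
                    f"({duration:g} s < {3 * self.window_s:g} s)"
                )


#: behaviors ordered easiest to hardest by the published mean ratings
_DIFFICULTY_ORDER = (
    BehaviorLabel.ROLL,
    BehaviorLabel.TAKEOFF,
    BehaviorLabel.LEVEL_FLIGHT,
    BehaviorLabel.TURN_AND_HOVER,
    BehaviorLabel.STALL,
    BehaviorLabel.SOMERSAULT,
)


def default_profiles() -> dict[BehaviorLabel, BehaviorProfile]:
    """Six profiles with monotone difficulty-driven parameter trends.

    Each profile's ``difficulty`` equals the packaged rating table's
    per-behavior mean.  Parameters step uniformly along the difficulty
    *ranking*, which keeps every trend strictly monotone in difficulty while
    leaving the closely-rated easy behaviors statistically separable.
    """
    means = load_difficulty_fixture().behavior_means()
    profiles: dict[BehaviorLabel, BehaviorProfile] = {}
    for rank, behavior in enumerate(_DIFFICULTY_ORDER):
        profiles[behavior] = BehaviorProfile(
            behavior=behavior,
            difficulty=float(means[behavior.to_string()]),
            mean_rr_ms=1000.0 - 60.0 * rank,
            rr_sd_ms=60.0 - 6.0 * rank,
            rr_ulf_frac=0.80 - 0.08 * rank,
            rr_lf_frac=0.50 - 0.05 * rank,
            rr_hf_frac=0.25 + 0.05 * rank,
            resp_rate_hz=0.18 + 0.036 * rank,
            scl_level_uS=2.0 + 1.0 * rank,
            scr_rate_per_min=4.0 + 1.0 * rank,
            emg_activation=0.90 - 0.12 * rank,
            skt_base_C=33.5 - 0.08 * rank,
        )
    return profiles


def default_schedule() -> tuple[tuple[BehaviorLabel, float], ...]:
    """One block per behavior: 240 s each, stall 180 s (~1380 s total)."""
    order = (
        BehaviorLabel.TAKEOFF,
        BehaviorLabel.LEVEL_FLIGHT,
        BehaviorLabel.TURN_AND_HOVER,
        BehaviorLabel.ROLL,
        BehaviorLabel.SOMERSAULT,
        BehaviorLabel.STALL,
    )
    return tuple(
        (b, 180.0 if b is BehaviorLabel.STALL else 240.0) for b in order
    )


def draw_rr_intervals(
    profile: BehaviorProfile, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Ground-truth RR intervals (ms) covering at least ``duration_s``.

    RR(t) = mean + band-structured modulators + white noise.  The modulators
    are sinusoids at fixed ULF/LF frequencies plus a respiration-coupled HF
    component, with amplitudes tied to ``rr_sd_ms`` so zero variance yields a
    perfectly regular rhythm.  Called first by :func:`simulate_ecg`, so tests
    can regenerate the truth from an identically-seeded generator.
    """
    mean = profile.mean_rr_ms
    sd = profile.rr_sd_ms
    phases = rng.uniform(0, 2 * np.pi, size=3)
    n_max = int(np.ceil(duration_s * 1000.0 / max(mean - 4 * sd, 300.0))) + 4
    white = rng.normal(0.0, sd * profile.rr_white_frac, size=n_max)
    rr = np.empty(n_max)
    t = 0.0
    for k in range(n_max):
        mod = (
            sd * profile.rr_ulf_frac * np.sin(2 * np.pi * ULF_MOD_HZ * t + phases[0])
            + sd * profile.rr_lf_frac * np.sin(2 * np.pi * LF_MOD_HZ * t + phases[1])
            + sd
            * profile.rr_hf_frac
            * np.sin(2 * np.pi * profile.resp_rate_hz * t + phases[2])
        )
        rr[k] = np.clip(mean + mod + white[k], 320.0, 1950.0)
        t += rr[k] / 1000.0
        if t > duration_s + 2.0:
            rr = rr[: k + 1]
            break
    return rr


# PQRST template: (time offset s, width s, amplitude) Gaussian bumps
_PQRST = (
    (-0.200, 0.030, 0.15),  # P
    (-0.035, 0.012, -0.12),  # Q
    (0.000, 0.014, 1.00),  # R
    (0.035, 0.012, -0.25),  # S
    (0.250, 0.055, 0.35),  # T
)


def simulate_ecg(
    profile: BehaviorProfile,
    duration_s: float,
    rate_hz: float = 512.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> ChannelRecording:
    """Quasi-periodic PQRST waveform with generator-known beat times."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    rr = draw_rr_intervals(profile, duration_s, rng)
    beat_times = np.cumsum(rr) / 1000.0
    n = int(round(duration_s * rate_hz))
    x = np.zeros(n)
    for tb in beat_times:
        if tb >= duration_s + 0.5:
            break
        for off, width, amp in _PQRST:
            centre = tb + off
            lo = int(np.floor((centre - 4 * width) * rate_hz))
            hi = int(np.ceil((centre + 4 * width) * rate_hz)) + 1
            lo_c, hi_c = max(lo, 0), min(hi, n)
            if lo_c >= hi_c:
                continue
            tt = np.arange(lo_c, hi_c) / rate_hz
            x[lo_c:hi_c] += amp * np.exp(-0.5 * ((tt - centre) / width) ** 2)
    x += rng.normal(0.0, profile.ecg_noise, size=n)
    return ChannelRecording(subject_id, ChannelKind.ECG, rate_hz, x)


def simulate_gsr(
    profile: BehaviorProfile,
    duration_s: float,
    rate_hz: float = 64.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> ChannelRecording:
    """Tonic level plus Poisson-arriving phasic responses plus noise."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration_s * rate_hz))
    x = np.full(n, profile.scl_level_uS)
    lam = profile.scr_rate_per_min / 60.0
    if lam > 0:
        n_events = rng.poisson(lam * duration_s)
        onsets = np.sort(rng.uniform(0, duration_s, size=n_events))
        amps = rng.exponential(SCR_AMP_US, size=n_events)
        impulse = np.zeros(n)
        idx = np.minimum((onsets * rate_hz).astype(int), n - 1)
        np.add.at(impulse, idx, amps)
        tk = np.arange(0, int((SCR_RISE_S + 6 * SCR_DECAY_S) * rate_hz)) / rate_hz
        kernel = (1 - np.exp(-tk / (SCR_RISE_S / 3))) * np.exp(-tk / SCR_DECAY_S)
        x = x + np.convolve(impulse, kernel)[:n]
    if profile.gsr_noise_uS > 0:
        x = x + rng.normal(0.0, profile.gsr_noise_uS, size=n)
    return ChannelRecording(subject_id, ChannelKind.GSR, rate_hz, x)


def simulate_emg(
    profile: BehaviorProfile,
    duration_s: float,
    rate_hz: float = 1024.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> ChannelRecording:
    """Broadband (20-400 Hz) noise amplitude-modulated by activation."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration_s * rate_hz))
    floor = rng.normal(0.0, EMG_NOISE_FLOOR, size=n)
    if profile.emg_activation <= 0:
        return ChannelRecording(subject_id, ChannelKind.EMG, rate_hz, floor)
    white = rng.normal(0.0, 1.0, size=n)
    hi = min(400.0, 0.45 * rate_hz)
    sos = sps.butter(4, [20.0, hi], btype="bandpass", fs=rate_hz, output="sos")
    band = sps.sosfiltfilt(sos, white)
    band /= np.sqrt(np.mean(band**2))
    t = np.arange(n) / rate_hz
    envelope = 1.0 + 0.2 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    x = floor + profile.emg_activation * EMG_FULL_SCALE * envelope * band
    return ChannelRecording(subject_id, ChannelKind.EMG, rate_hz, x)


def simulate_resp(
    profile: BehaviorProfile,
    duration_s: float,
    rate_hz: float = 64.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> ChannelRecording:
    """Sinusoid at the profile's breathing rate with slow amplitude/phase jitter."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    phase0 = rng.uniform(0, 2 * np.pi)
    # smooth phase jitter: integrated low-pass noise, small enough to keep
    # the spectral peak at the nominal rate
    jitter = rng.normal(0.0, 1.0, size=n)
    sos = sps.butter(2, 0.05, btype="lowpass", fs=rate_hz, output="sos")
    phase_jitter = 0.15 * sps.sosfiltfilt(sos, jitter)
    amp = RESP_AMP * (1.0 + 0.1 * np.sin(2 * np.pi * 0.01 * t + rng.uniform(0, 2 * np.pi)))
    x = RESP_OFFSET + amp * np.sin(
        2 * np.pi * profile.resp_rate_hz * t + phase0 + phase_jitter
    )
    if profile.resp_noise > 0:
        x = x + rng.normal(0.0, profile.resp_noise, size=n)
    return ChannelRecording(subject_id, ChannelKind.RESP, rate_hz, x)


def simulate_skt(
    profile: BehaviorProfile,
    duration_s: float,
    rate_hz: float = 32.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> ChannelRecording:
    """Baseline temperature plus a mean-reverting bounded random walk."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration_s * rate_hz))
    max_step = 0.09 / rate_hz  # keeps |dT/dt| < 0.1 degC/s
    steps = np.clip(
        rng.normal(0.0, 0.01 / rate_hz, size=n), -max_step, max_step
    )
    walk = np.empty(n)
    w = 0.0
    theta = 0.02 / rate_hz  # mean reversion
    for i in range(n):
        w += steps[i] - theta * w
        walk[i] = w
    x = profile.skt_base_C + walk
    if profile.skt_noise_C > 0:
        x = x + rng.normal(0.0, profile.skt_noise_C, size=n)
    return ChannelRecording(subject_id, ChannelKind.SKT, rate_hz, x)


_SIMULATORS = {
    ChannelKind.ECG: simulate_ecg,
    ChannelKind.GSR: simulate_gsr,
    ChannelKind.EMG: simulate_emg,
    ChannelKind.RESP: simulate_resp,
    ChannelKind.SKT: simulate_skt,
}

#: profile parameters subject to per-subject multiplicative jitter
_JITTERED_PARAMS = (
    "mean_rr_ms",
    "rr_sd_ms",
    "resp_rate_hz",
    "scl_level_uS",
    "scr_rate_per_min",
    "emg_activation",
)


def _jitter_profiles(
    profiles: dict[BehaviorLabel, BehaviorProfile],
    jitter_sd: float,
    rng: np.random.Generator,
) -> dict[BehaviorLabel, BehaviorProfile]:
    """One log-normal factor per parameter per subject, shared across
    behaviors so within-subject difficulty orderings are preserved."""
    factors = {
        p: float(rng.lognormal(0.0, jitter_sd)) for p in _JITTERED_PARAMS
    }
    out = {}
    for behavior, prof in profiles.items():
        updates = {}
        for p, f in factors.items():
            v = getattr(prof, p) * f
            if p == "mean_rr_ms":
                v = float(np.clip(v, 400.0, 1500.0))
            elif p == "resp_rate_hz":
                v = float(np.clip(v, 0.1, 1.0))
            elif p == "emg_activation":
                v = float(np.clip(v, 0.0, 1.0))
            updates[p] = v
        out[behavior] = replace(prof, **updates)
    return out


def simulate_recording_set(
    schedule: Sequence[tuple[BehaviorLabel, float]],
    profiles: dict[BehaviorLabel, BehaviorProfile],
    rng: np.random.Generator,
    subject_id: str = "sim",
    artifact_rate_per_min: float = 0.0,
) -> LabeledRecordingSet:
    """Simulate one subject: per-segment channel blocks concatenated in time."""
    pieces: dict[ChannelKind, list[np.ndarray]] = {k: [] for k in ChannelKind}
    segments = []
    t0 = 0.0
    for behavior, duration in schedule:
        prof = profiles[behavior]
        for kind in ChannelKind:
            rec = _SIMULATORS[kind](
                prof, duration, kind.native_rate, rng, subject_id
            )
            pieces[kind].append(rec.samples)
        segments.append((t0, t0 + duration, behavior))
        t0 += duration
    channels = {}
    for kind in ChannelKind:
        samples = np.concatenate(pieces[kind])
        if artifact_rate_per_min > 0 and kind in (ChannelKind.GSR, ChannelKind.SKT):
            samples = _inject_artifacts(samples, kind.native_rate, artifact_rate_per_min, rng)
        channels[kind] = ChannelRecording(subject_id, kind, kind.native_rate, samples)
    return LabeledRecordingSet(
        subject_id=subject_id, channels=channels, label_track=LabelTrack(segments)
    )


def _inject_artifacts(
    x: np.ndarray, rate: float, rate_per_min: float, rng: np.random.Generator
) -> np.ndarray:
    """White impulse spikes and short NaN dropouts for ectopic-handling tests."""
    x = x.copy()
    n_events = rng.poisson(rate_per_min / 60.0 * x.size / rate)
    idx = rng.integers(0, x.size, size=n_events)
    kind = rng.uniform(size=n_events)
    for i, u in zip(idx, kind):
        if u < 0.5:
            x[i] *= 1.0 + rng.uniform(0.3, 1.5) * rng.choice([-1.0, 1.0])
        else:
            x[i : i + int(0.1 * rate) + 1] = np.nan
    return x


def simulate_cohort(plan: SimPlan) -> list[LabeledRecordingSet]:
    """One labeled recording set per subject, reproducible from the seed."""
    seeds = np.random.SeedSequence(plan.seed).spawn(plan.subjects)
    cohort = []
    for i, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        profiles = _jitter_profiles(plan.profiles, plan.jitter_sd, rng)
        subject_id = f"Subject {i + 1}"
        rset = simulate_recording_set(
            plan.schedule,
            profiles,
            rng,
            subject_id=subject_id,
            artifact_rate_per_min=plan.artifact_rate_per_min,
        )
        cohort.append(rset)
        logger.info("simulated %s: %.0f s", subject_id, rset.duration)
    return cohort
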