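import math

import numpy as np
import pytest

from physiofuse.features import (
    FEATURE_NAMES,
    emg_features,
    fuse,
    hrv_freq_features,
    hrv_time_features,
    make_windows,
    resp_features,
    stat_features,
)
from physiofuse.model import BehaviorLabel, ChannelKind, ChannelRecording, LabeledRecordingSet, LabelTrack
from physiofuse.preprocess import BeatSeries


def _beats_from_rr(rr_ms):
    times = np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
    return BeatSeries(times)


def _brute_stats(x):
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    rms = math.sqrt(sum(v**2 for v in x) / n)
    return mean, std, rms


class TestCanonicalOrder:
    def test_28_features(self):
        assert len(FEATURE_NAMES) == 28
        assert len(set(FEATURE_NAMES)) == 28

    def test_block_sizes(self):
        ecg = [n for n in FEATURE_NAMES[:13]]
        assert ecg[0] == "ecg_value" and ecg[-1] == "lf_hf"
        assert FEATURE_NAMES[13:16] == ("sc_value", "sc_mean", "sc_std")
        assert FEATURE_NAMES[16:23][0] == "emg_value"
        assert FEATURE_NAMES[23:27][-1] == "resp_freq"
        assert FEATURE_NAMES[27] == "skt_value"


class TestStatFeatures:
    def test_constant(self):
        assert stat_features(np.array([3.0, 3.0, 3.0])) == (3.0, 0.0, 3.0)

    def test_plus_minus_one(self):
        assert stat_features(np.array([1.0, -1.0])) == (0.0, 1.0, 1.0)

    def test_rr_like(self):
        x = [800.0, 810.0, 790.0, 805.0]
        mean, std, rms = stat_features(np.array(x))
        bm, bs, br = _brute_stats(x)
        assert mean == pytest.approx(801.25)
        assert std == pytest.approx(bs, rel=1e-12)
        assert rms == pytest.approx(br, rel=1e-12)

    def test_oracle_equivalence(self, rng):
        """Implementation vs direct-summation oracle on 100 random windows."""
        for _ in range(100):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 3), size=rng.integers(2, 50))
            got = stat_features(x)
            want = _brute_stats(list(x))
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-9)

    def test_empty(self):
        assert all(math.isnan(v) for v in stat_features(np.array([])))


class TestHrvTime:
    def test_regular_rhythm(self):
        out = hrv_time_features(_beats_from_rr([800, 800, 800]))
        assert out["nn"] == pytest.approx(800)
        assert out["hr"] == pytest.approx(75)
        assert out["sdnn"] == pytest.approx(0, abs=1e-9)
        assert out["rmssd"] == pytest.approx(0, abs=1e-9)
        assert out["pnn50"] == 0

    def test_alternans(self):
        out = hrv_time_features(_beats_from_rr([800, 860, 800]))
        assert out["pnn50"] == pytest.approx(100)
        assert out["rmssd"] == pytest.approx(60)

    def test_strict_threshold(self):
        # successive difference of exactly 20 ms is NOT > 20
        out = hrv_time_features(_beats_from_rr([790, 810]))
        assert out["pnn20"] == 0
        assert out["pnn50"] == 0

    def test_too_few_intervals(self):
        out = hrv_time_features(_beats_from_rr([800]))
        assert all(math.isnan(v) for v in out.values())

    def test_pnn_ordering_property(self, rng):
        for _ in range(50):
            rr = rng.uniform(600, 1100, size=rng.integers(3, 40))
            out = hrv_time_features(_beats_from_rr(rr))
            assert out["pnn50"] <= out["pnn20"]

    def test_rmssd_sdsd_identity(self, rng):
        # RMSSD^2 = SDSD^2 + mean(diff)^2 exactly, with population SDs
        for _ in range(50):
            rr = rng.uniform(600, 1100, size=10)
            out = hrv_time_features(_beats_from_rr(rr))
            d = np.diff(rr)
            assert out["rmssd"] ** 2 == pytest.approx(
                out["sdsd"] ** 2 + np.mean(d) ** 2, rel=1e-9
            )


def _modulated_beats(freq_hz, duration_s=300.0, amp_ms=50.0, mean_ms=800.0):
    times = [0.0]
    while times[-1] < duration_s:
        t = times[-1]
        rr = mean_ms + amp_ms * math.sin(2 * math.pi * freq_hz * t)
        times.append(t + rr / 1000.0)
    return BeatSeries(np.array(times))


class TestHrvFreq:
    def test_lf_concentration(self):
        beats = _modulated_beats(0.10)
        out = hrv_freq_features(beats, 300.0)
        total = out["ulf"] + out["vlf"] + out["lf"] + out["hf"]
        assert out["lf"] / total >= 0.90

    def test_hf_dominant(self):
        beats = _modulated_beats(0.25)
        out = hrv_freq_features(beats, 300.0)
        assert out["hf"] > out["lf"]
        assert out["lf_hf"] < 0.2

    def test_short_buffer_drops_slow_bands(self):
        beats = _modulated_beats(0.25, duration_s=90.0)
        out = hrv_freq_features(beats, 90.0)
        assert math.isnan(out["ulf"]) and math.isnan(out["vlf"])
        assert math.isfinite(out["lf_hf"])

    def test_too_few_beats(self):
        out = hrv_freq_features(BeatSeries(np.array([0.0, 0.8])), 30.0)
        assert all(math.isnan(v) for v in out.values())


class TestEmgFeatures:
    def test_flat_psd(self, rng):
        # white noise at 400 Hz: PSD flat on [0, 200] -> MF = MPF = 100
        x = rng.normal(size=400 * 120)
        out = emg_features(x, 400.0)
        assert out["emg_mf"] == pytest.approx(100.0, abs=5.0)
        assert out["emg_mpf"] == pytest.approx(100.0, abs=5.0)

    def test_single_tone(self):
        t = np.arange(30 * 1024) / 1024.0
        x = np.sin(2 * np.pi * 120.0 * t)
        out = emg_features(x, 1024.0)
        assert out["emg_mf"] == pytest.approx(120.0, abs=1.0)
        assert out["emg_mpf"] == pytest.approx(120.0, abs=1.0)

    def test_iemg_integral(self):
        x = np.full(30 * 1024, 2.0) * np.sign(np.sin(np.arange(30 * 1024)))
        x[x == 0] = 2.0
        out = emg_features(x, 1024.0)
        assert out["iemg"] == pytest.approx(60.0, rel=1e-9)  # |x|=2 over 30 s
        assert out["emg_mean"] == pytest.approx(2.0)  # rectified mean

    def test_zero_power(self):
        out = emg_features(np.zeros(1024), 1024.0)
        assert math.isnan(out["emg_mf"]) and math.isnan(out["emg_mpf"])


class TestRespFeatures:
    def test_sinusoid_frequency(self):
        t = np.arange(30 * 64) / 64.0
        x = 0.5 + np.sin(2 * np.pi * 0.3 * t)
        out = resp_features(x, 64.0)
        assert out["resp_freq"] == pytest.approx(0.3, abs=1.0 / 30.0)
        assert out["resp_mean"] == pytest.approx(0.5, abs=0.02)

    def test_constant_missing_frequency(self):
        out = resp_features(np.full(30 * 64, 1.0), 64.0)
        assert math.isnan(out["resp_freq"])

    def test_value_is_last_sample(self):
        x = np.linspace(0, 1, 64)
        assert resp_features(x, 64.0)["resp_value"] == pytest.approx(1.0)


class TestMakeWindows:
    def _single_behavior_set(self, duration=240.0):
        rng = np.random.default_rng(0)
        channels = {
            k: ChannelRecording(
                "s", k, k.native_rate, rng.normal(size=int(duration * k.native_rate))
            )
            for k in ChannelKind
        }
        track = LabelTrack([(0.0, duration, BehaviorLabel.ROLL)])
        return LabeledRecordingSet("s", channels, track)

    def test_count(self):
        windows = make_windows(self._single_behavior_set(240.0))
        assert len(windows) == 22  # floor((240-30)/10)+1

    def test_too_short(self):
        windows = make_windows(self._single_behavior_set(29.0))
        assert windows == []

    def test_majority_label(self):
        rset = self._single_behavior_set(60.0)
        track = LabelTrack(
            [(0.0, 20.0, BehaviorLabel.TAKEOFF), (20.0, 60.0, BehaviorLabel.ROLL)]
        )
        rset = LabeledRecordingSet("s", rset.channels, track)
        windows = dict(make_windows(rset))
        assert windows[0.0] is BehaviorLabel.TAKEOFF  # 20 s takeoff vs 10 s roll
        assert windows[10.0] is BehaviorLabel.ROLL

    def test_rejected_tile_drops_windows(self):
        rset = self._single_behavior_set(120.0)
        windows = make_windows(rset, rejected=[(30.0, 60.0)])
        starts = [s for s, _ in windows]
        assert all(not (s < 60.0 and s + 30.0 > 30.0) for s in starts)


class TestFuse:
    def test_every_row_has_28_features(self, one_subject_matrix):
        df = one_subject_matrix.frame
        assert list(df.columns) == ["subject", "window_start_s", *FEATURE_NAMES, "label"]
        assert len(df) > 0
        assert len(df.columns) == 31

    def test_all_behaviors_present(self, one_subject_matrix):
        assert set(one_subject_matrix.frame["label"]) == {
            b.to_string() for b in BehaviorLabel
        }

    def test_complete_rows_have_finite_features(self, one_subject_matrix):
        complete = one_subject_matrix.complete_rows()
        assert len(complete) > 0
        assert np.isfinite(complete.features().to_numpy()).all()

    def test_invariant_ranges(self, one_subject_matrix):
        df = one_subject_matrix.complete_rows().frame
        for col in ("pnn50", "pnn20"):
            assert df[col].between(0, 100).all()
        for col in ("sdnn", "rmssd", "sdsd", "ulf", "vlf", "lf", "hf", "lf_hf"):
            assert (df[col] >= 0).all()
        assert (df["pnn50"] <= df["pnn20"]).all()
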