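import numpy as np
import pytest
from scipy import signal as sps

from physiofuse import _wavelet
from physiofuse.model import ChannelKind, ChannelRecording
from physiofuse.preprocess import (
    BeatSeries,
    clean_channel,
    detect_ectopic,
    detect_r_peaks,
    downsample,
    filter_channel,
    impute,
    reject_windows,
    zscore_normalize,
)


class TestZScore:
    def test_closed_form(self):
        out = zscore_normalize(np.array([1.0, 2.0, 3.0]))
        assert out == pytest.approx([-1.224744871391589, 0.0, 1.224744871391589])

    def test_moments(self, rng):
        out = zscore_normalize(rng.normal(3.0, 2.0, size=1000))
        assert abs(out.mean()) < 1e-9
        assert abs(out.std() - 1.0) < 1e-9

    def test_idempotent(self, rng):
        x = rng.normal(size=200)
        once = zscore_normalize(x)
        assert np.allclose(zscore_normalize(once), once, atol=1e-12)

    def test_scale_shift_invariant(self, rng):
        x = rng.normal(size=100)
        assert np.allclose(zscore_normalize(3.5 * x + 7.0), zscore_normalize(x))

    def test_constant(self):
        with pytest.raises(ValueError, match="constant signal"):
            zscore_normalize(np.array([5.0, 5.0, 5.0]))


class TestDetectEctopic:
    def test_below_threshold(self):
        mask = detect_ectopic(np.array([100.0, 110.0, 100.0]), 0.20)
        assert mask.tolist() == [False, False, False]

    def test_spike_flagged(self):
        mask = detect_ectopic(np.array([100.0, 130.0, 100.0]), 0.20)
        assert mask.tolist() == [False, True, False]

    def test_accepted_reference(self):
        # 121 vs 100 is 21% -> ectopic; 100 is then compared to the last
        # *accepted* value 100 (0%), not to 121
        mask = detect_ectopic(np.array([100.0, 121.0, 100.0]), 0.20)
        assert mask.tolist() == [False, True, False]

    def test_first_sample_never_ectopic(self):
        assert not detect_ectopic(np.array([5.0, 5.0]), 0.2)[0]

    def test_nonfinite_flagged(self):
        mask = detect_ectopic(np.array([1.0, np.nan, 1.0, np.inf]), 0.2)
        assert mask.tolist() == [False, True, False, True]

    def test_zero_reference(self):
        mask = detect_ectopic(np.array([0.0, 1.0, 1.0]), 0.2)
        assert mask[1]  # undefined ratio vs 0 reference

    def test_reanchor_after_level_step(self):
        # a sustained step must not cascade forever
        x = np.concatenate([np.full(20, 100.0), np.full(50, 150.0)])
        mask = detect_ectopic(x, 0.20, max_run=8)
        assert mask[20]
        assert not mask[-1]
        assert mask.sum() <= 9

    def test_literal_rule_freezes(self):
        x = np.concatenate([np.full(5, 100.0), np.full(10, 150.0)])
        mask = detect_ectopic(x, 0.20, max_run=None)
        assert mask[5:].all()

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            detect_ectopic(np.array([1.0, 2.0]), 1.5)


class TestRejectWindows:
    def test_over_threshold_removed(self):
        x = np.zeros(60)
        mask = np.zeros(60, dtype=bool)
        mask[:8] = True  # 8/30 = 26.7% of the first tile
        out, rejected = reject_windows(x, mask, window_s=30, rate=1.0)
        assert rejected == [(0.0, 30.0)]
        assert np.isnan(out[:30]).all()
        assert np.isfinite(out[30:]).all()

    def test_exactly_at_threshold_kept(self):
        mask = np.zeros(30, dtype=bool)
        mask[:6] = True  # exactly 20%: strict inequality keeps it
        _, rejected = reject_windows(np.zeros(30), mask, window_s=30, rate=1.0)
        assert rejected == []

    def test_no_flags(self):
        x = np.arange(90.0)
        out, rejected = reject_windows(x, np.zeros(90, dtype=bool), rate=1.0)
        assert rejected == []
        assert np.array_equal(out, x)


class TestImpute:
    def test_linear_ramp(self):
        x = np.arange(100.0)
        mask = np.zeros(100, dtype=bool)
        mask[50] = True
        out = impute(x, mask, w=11)
        assert out[50] == pytest.approx(50.0)

    def test_boundary_shrink(self):
        x = np.arange(20.0)
        mask = np.zeros(20, dtype=bool)
        mask[0] = True
        out = impute(x, mask, w=11)
        assert out[0] == pytest.approx(np.mean(np.arange(1, 6)))

    def test_identity_without_flags(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(impute(x, np.zeros(50, dtype=bool)), x)

    def test_all_neighbors_flagged_falls_back(self):
        x = np.full(30, 7.0)
        x[10:25] = np.nan
        mask = np.zeros(30, dtype=bool)
        mask[10:25] = True
        out = impute(x, mask, w=11)
        assert np.isfinite(out).all()
        assert out[17] == pytest.approx(7.0)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            impute(np.zeros(5), np.zeros(5, dtype=bool), w=4)


class TestFilterChannel:
    def test_gsr_nyquist_guard(self):
        x = np.random.default_rng(0).normal(size=640)
        _, log = filter_channel(x, ChannelKind.GSR, 64.0)
        assert any("bandstop:50.0Hz skipped" in entry for entry in log)
        assert "lowpass:5.0Hz" in log

    def test_skt_unreliable_row_skipped(self):
        x = np.random.default_rng(0).normal(size=320)
        _, log = filter_channel(x, ChannelKind.SKT, 32.0)
        assert any("highpass:5.0Hz skipped" in e for e in log)
        assert any("lowpass:200.0Hz skipped" in e for e in log)

    def test_notch_attenuation(self):
        rate = 512.0
        t = np.arange(int(10 * rate)) / rate
        tone = np.sin(2 * np.pi * 50.0 * t)
        out, log = filter_channel(tone, ChannelKind.ECG, rate)
        assert "bandstop:50.0Hz" in log
        f, p = sps.periodogram(out, fs=rate)
        f0, p0 = sps.periodogram(tone, fs=rate)
        band = (f > 49) & (f < 51)
        atten_db = 10 * np.log10(p0[band].sum() / max(p[band].sum(), 1e-300))
        assert atten_db >= 20.0

    def test_highpass_removes_dc(self):
        rng = np.random.default_rng(1)
        x = 5.0 + rng.normal(0, 0.1, size=5120)
        out, _ = filter_channel(x, ChannelKind.ECG, 512.0)
        assert abs(np.mean(out)) < 0.05

    @pytest.mark.parametrize("kind", list(ChannelKind))
    def test_length_preserved_and_nyquist_guard(self, kind, rng):
        rate = kind.native_rate
        x = rng.normal(size=int(35 * rate))
        out, log = filter_channel(x, kind, rate)
        assert out.size == x.size
        for entry in log:
            if "skipped" in entry or ":" not in entry:
                continue
            stage, _, rest = entry.partition(":")
            if stage in ("highpass", "lowpass", "bandstop"):
                cutoff = float(rest.rstrip("Hz"))
                assert cutoff < rate / 2


class TestWavelet:
    @pytest.mark.parametrize("n", [64, 101, 4096])
    def test_round_trip(self, n, rng):
        x = rng.normal(size=n)
        coeffs = _wavelet.wavedec(x, 4)
        assert np.allclose(_wavelet.waverec(coeffs, n), x, atol=1e-10)

    def test_denoise_reduces_noise(self, rng):
        t = np.arange(8192) / 512
        clean = np.sin(2 * np.pi * 2 * t)
        noisy = clean + rng.normal(0, 0.2, size=clean.size)
        den = _wavelet.denoise(noisy, 6)
        assert np.sqrt(np.mean((den - clean) ** 2)) < 0.5 * np.sqrt(
            np.mean((noisy - clean) ** 2)
        )


class TestBeatSeries:
    def test_rr_and_gate(self):
        beats = BeatSeries(np.array([0.0, 0.8, 1.6, 4.0]))
        assert np.allclose(beats.rr_intervals_ms, [800, 800, 2400])
        assert beats.rr_valid.tolist() == [True, True, False]

    def test_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            BeatSeries(np.array([0.0, 1.0, 0.5]))

    def test_flat_signal_no_peaks(self):
        beats = detect_r_peaks(np.zeros(5120), 512.0)
        assert beats.r_peak_times_s.size == 0


class TestDownsample:
    def test_constant(self):
        out = downsample(np.full(5120, 3.0), 512.0, 2.0)
        assert out.size == 20
        assert np.allclose(out, 3.0)

    def test_ramp_bins(self):
        out = downsample(np.arange(640.0), 64.0, 2.0)
        assert out.size == 20
        assert out[0] == pytest.approx(np.mean(np.arange(32)))  # 15.5

    def test_empty(self):
        assert downsample(np.array([]), 64.0).size == 0


class TestCleanChannel:
    def test_no_nonfinite_after_cleaning(self, rng):
        x = 3.0 + 0.2 * np.sin(np.arange(64 * 90) / 64)
        x[100] = np.nan
        x[5000] = 30.0  # huge spike
        rec = ChannelRecording("s", ChannelKind.GSR, 64.0, x)
        clean = clean_channel(rec)
        assert np.isfinite(clean.samples).all()
        assert clean.imputed_count >= 2

    def test_rerun_bit_identical(self, rng):
        x = 3.0 + rng.normal(0, 0.01, size=64 * 60)
        rec = ChannelRecording("s", ChannelKind.GSR, 64.0, x)
        a = clean_channel(rec)
        b = clean_channel(rec)
        assert np.array_equal(a.samples, b.samples)
        assert a.filter_log == b.filter_log
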