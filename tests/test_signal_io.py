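"""Preprocessing (DC removal, downsampling, band-pass) and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from hippoephys.signal_io import (
    bandpass,
    downsample,
    read_events,
    read_signal,
    read_spikes,
    remove_dc,
    write_events,
    write_signal,
    write_spikes,
)
from hippoephys.types import ContinuousSignal, SpikeTrain

FS = 1250.0


def brute_force_moving_mean(x, win):
    """Independent oracle: per-sample mean over a shrinking centered window."""
    half = win // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(i - half, 0), min(i + half, len(x) - 1)
        out[i] = np.mean(x[lo : hi + 1])
    return out


class TestRemoveDc:
    def test_constant_becomes_zero(self):
        sig = ContinuousSignal(np.full(5000, 3.7), FS)
        out = remove_dc(sig)
        assert np.allclose(out.samples, 0.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(800)
        sig = ContinuousSignal(x, FS)
        out = remove_dc(sig, window_s=0.1)
        win = int(round(0.1 * FS))
        expected = x - brute_force_moving_mean(x, win)
        assert np.allclose(out.samples, expected, atol=1e-12)

    def test_sine_recovered_from_drift(self):
        t = np.arange(int(6 * FS)) / FS
        sine = np.sin(2 * np.pi * 8 * t)
        drift = 0.5 * t  # linear DC drift
        out = remove_dc(ContinuousSignal(sine + drift, FS)).samples
        mid = slice(int(FS), int(5 * FS))
        residual = out[mid] - sine[mid]
        # residual drift well below the original drift span
        assert np.max(np.abs(residual)) < 0.05 * np.max(drift)

    def test_idempotent_on_trend_content(self):
        """On trend-like input (the operator's target) one pass removes
        everything in the interior, so a second pass is a no-op."""
        t = np.arange(4000) / FS
        sig = ContinuousSignal(2.0 + 0.7 * t, FS)
        once = remove_dc(sig)
        win = int(round(0.3 * FS))
        interior = slice(win, -win)
        rms_in = np.sqrt(np.mean(sig.samples**2))
        assert np.max(np.abs(once.samples[interior])) < 1e-9 * rms_in
        twice = remove_dc(once)
        assert np.max(np.abs(twice.samples[interior] - once.samples[interior])) < 1e-9 * rms_in

    def test_second_pass_nearly_neutral_on_oscillations(self):
        t = np.arange(int(8 * FS)) / FS
        sig = ContinuousSignal(np.sin(2 * np.pi * 10 * t), FS)
        once = remove_dc(sig)
        twice = remove_dc(once)
        rms = np.sqrt(np.mean(once.samples**2))
        assert np.sqrt(np.mean((twice.samples - once.samples) ** 2)) < 0.05 * rms

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(ValueError):
            remove_dc(ContinuousSignal(np.zeros(100), FS), window_s=1.0)


class TestDownsample:
    def test_factor_16_from_20khz(self):
        t = np.arange(int(2 * 20000)) / 20000
        sig = ContinuousSignal(np.sin(2 * np.pi * 7 * t), 20000.0)
        out = downsample(sig, 1250.0)
        assert out.fs == 1250.0
        assert abs(out.duration - sig.duration) <= 1.0 / 1250.0
        # 7 Hz amplitude preserved within 1%
        mid = out.samples[len(out.samples) // 4 : -len(out.samples) // 4]
        assert abs(np.max(mid) - 1.0) < 0.01

    def test_identity_rate(self):
        rng = np.random.default_rng(2)
        sig = ContinuousSignal(rng.standard_normal(1000), FS)
        out = downsample(sig, FS)
        assert np.allclose(out.samples, sig.samples)

    def test_bad_target_errors(self):
        sig = ContinuousSignal(np.zeros(100), FS)
        with pytest.raises(ValueError):
            downsample(sig, -5)
        with pytest.raises(ValueError):
            downsample(sig, 2 * FS)


class TestBandpass:
    def test_passband_amplitude_and_phase(self, sine_factory):
        sig = sine_factory(8.0, duration_s=20.0)
        out = bandpass(sig, 5, 12)
        mid = slice(int(5 * FS), int(15 * FS))
        amp = np.max(np.abs(out.samples[mid]))
        assert abs(amp - 1.0) < 0.02
        # zero-phase: cross-correlation peak at zero lag
        xc = np.correlate(out.samples[mid], sig.samples[mid], "full")
        lag = np.argmax(xc) - (len(xc) // 2)
        assert abs(lag) / FS * 8 * 360 < 1.0  # < 1 degree at 8 Hz

    def test_stopband_attenuation(self, sine_factory):
        sig = sine_factory(3.0, duration_s=20.0)
        out = bandpass(sig, 5, 12)
        mid = slice(int(5 * FS), int(15 * FS))
        atten_db = -20 * np.log10(np.max(np.abs(out.samples[mid])))
        assert atten_db >= 20

    def test_repeat_filtering_stable(self, sine_factory):
        sig = sine_factory(8.0, duration_s=10.0)
        once = bandpass(sig, 5, 12)
        twice = bandpass(once, 5, 12)
        mid = slice(int(2 * FS), int(8 * FS))
        assert np.allclose(twice.samples[mid], once.samples[mid], atol=0.02)

    def test_invalid_band_errors(self, sine_factory):
        sig = sine_factory(8.0, duration_s=2.0)
        with pytest.raises(ValueError):
            bandpass(sig, 12, 5)
        with pytest.raises(ValueError):
            bandpass(sig, 100, 700)


class TestRoundTrips:
    def test_signal_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        sig = ContinuousSignal(rng.standard_normal(500), FS, t0=1.5, channel_id="ca1")
        write_signal(sig, tmp_path / "sig")
        back = read_signal(tmp_path / "sig")
        assert np.array_equal(back.samples, sig.samples)
        assert (back.fs, back.t0, back.channel_id) == (sig.fs, sig.t0, sig.channel_id)

    def test_events_round_trip_and_validation(self, tmp_path):
        ev = pd.DataFrame(
            {
                "time_s": [0.0, 1.0, 2.0, 2.5],
                "event_type": ["trial_start", "reward", "trial_start", "teleport"],
                "value": [0, 0, 1, 1],
            }
        )
        write_events(ev, tmp_path / "ev.csv")
        back = read_events(tmp_path / "ev.csv")
        assert list(back["event_type"]) == list(ev["event_type"])

    def test_non_monotonic_events_rejected(self, tmp_path):
        ev = pd.DataFrame(
            {
                "time_s": [2.0, 1.0],
                "event_type": ["reward", "reward"],
                "value": [0, 1],
            }
        )
        write_events(ev, tmp_path / "bad.csv")
        with pytest.raises(ValueError, match="non-monotonic"):
            read_events(tmp_path / "bad.csv")

    def test_spikes_round_trip_at_declared_precision(self, tmp_path):
        rng = np.random.default_rng(4)
        times = np.round(np.sort(rng.uniform(0, 100, 200)), 5)
        trains = [SpikeTrain(times, unit_id="u001"), SpikeTrain(np.empty(0), "u002")]
        write_spikes(trains, tmp_path / "sp.csv")
        back = read_spikes(tmp_path / "sp.csv")
        assert np.array_equal(back[0].times, times)

    def test_shuffled_spike_rows_rejected(self, tmp_path):
        (tmp_path / "sp.csv").write_text(
            "unit_id,time_s\nu1,2.00000\nu1,1.00000\n"
        )
        with pytest.raises(ValueError, match="non-monotonic"):
            read_spikes(tmp_path / "sp.csv")

    def test_empty_train_writes_header_only(self, tmp_path):
        write_spikes([SpikeTrain(np.empty(0), "u0")], tmp_path / "e.csv")
        assert (tmp_path / "e.csv").read_text().strip() == "unit_id,time_s"
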