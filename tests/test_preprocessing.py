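"""Window pipeline: slicing, detrend, high-pass, notch, rejection."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emgtaste as e
from emgtaste.errors import ConfigError, StageOrderError

from conftest import make_window, silent_config

FS = 1000.0
T1 = np.arange(1000) / FS


def _recording(samples, duration=None, fs=FS):
    samples = np.atleast_2d(samples)
    return e.RawRecording(
        samples=samples,
        fs=fs,
        participant_id="P1",
        session_id=1,
        taste="no",
        duration=duration if duration is not None else samples.shape[1] / fs,
    )


class TestSliceWindows:
    @pytest.mark.parametrize("duration, expected", [(8.0, 8), (8.5, 8), (0.5, 0)])
    def test_window_count_with_trailing_partial_dropped(self, duration, expected, pre_config):
        T = int(duration * FS)
        rec = _recording(np.zeros((6, T)), duration=duration)
        windows = e.slice_windows(rec, pre_config)
        assert len(windows) == expected

    def test_windows_are_in_temporal_order_with_provenance(self, pre_config):
        x = np.arange(3000, dtype=float)[None, :] * np.ones((6, 1))
        rec = _recording(x)
        windows = e.slice_windows(rec, pre_config)
        starts = [w.provenance["start_sample"] for w in windows]
        assert starts == [0, 1000, 2000]
        assert [w.provenance["window"] for w in windows] == [0, 1, 2]
        assert np.array_equal(windows[1].samples[0], x[0, 1000:2000])


class TestDetrend:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        coeffs=st.lists(st.floats(-500, 500), min_size=1, max_size=5),
        degree=st.integers(0, 4),
    )
    def test_annihilates_polynomials_of_lower_or_equal_degree(self, coeffs, degree):
        """Any degree-<=4 polynomial input leaves residual < 1e-6 uV."""
        coeffs = coeffs[: degree + 1]
        t = np.linspace(-1, 1, 1000)
        poly = np.polynomial.polynomial.polyval(t, np.asarray(coeffs))
        w = make_window(np.tile(poly, (6, 1)))
        out = e.detrend_poly(w, degree=4)
        assert np.abs(out.samples).max() < 1e-6

    def test_zero_input_stays_zero(self):
        out = e.detrend_poly(make_window(np.zeros((6, 1000))))
        assert np.all(out.samples == 0.0)

    def test_recovers_sinusoid_riding_on_quartic_trend(self):
        """Quartic + unit 50 Hz tone: the trend is annihilated exactly and
        the output equals the tone minus its own (small) projection onto the
        polynomial basis -- an independent least-squares oracle."""
        t = np.linspace(-1, 1, 1000)
        trend = 200 - 150 * t + 80 * t**2 + 40 * t**3 - 25 * t**4
        tone = np.sin(2 * np.pi * 50 * T1 + 0.4)
        out = e.detrend_poly(make_window(trend + tone))
        V = np.column_stack([t**k for k in range(5)])
        proj, *_ = np.linalg.lstsq(V, tone, rcond=None)
        oracle = tone - V @ proj
        assert np.abs(out.samples[0] - oracle).max() < 1e-9
        # the projection itself is tiny: the tone survives within 0.1 uV
        assert np.abs(out.samples[0] - tone).max() < 0.1

    def test_requires_raw_stage_and_finite_values(self):
        w = make_window(np.zeros((6, 1000)), stage="detrended")
        with pytest.raises(StageOrderError):
            e.detrend_poly(w)
        bad = make_window(np.zeros((1, 1000)))
        bad.samples[0, 3] = np.nan
        with pytest.raises(ConfigError, match="non-finite"):
            e.detrend_poly(bad)


class TestHighpass:
    def test_dc_gain_is_zero_away_from_edges(self):
        w = make_window(np.full((1, 1000), 100.0), stage="detrended")
        out = e.highpass_butterworth(w)
        assert np.abs(out.samples[0, 250:750]).max() < 0.1

    def test_passband_50hz_amplitude_within_one_percent(self):
        w = make_window(np.sin(2 * np.pi * 50 * T1 + 0.3), stage="detrended")
        out = e.highpass_butterworth(w)
        amp = np.abs(out.samples[0, 300:700]).max()
        assert 0.99 < amp < 1.01

    def test_stopband_1hz_steady_state_below_1e6(self):
        """Zero-phase gain at 1 Hz is |H|^2 ~ 1e-8; measured mid-signal on a
        long window where the response reaches steady state."""
        t8 = np.arange(8000) / FS
        w = make_window(np.sin(2 * np.pi * 1 * t8), stage="detrended")
        out = e.highpass_butterworth(w)
        assert np.abs(out.samples[0, 3000:5000]).max() < 1e-6

    def test_zero_phase_gain_matches_closed_form_butterworth(self):
        from scipy import signal as sps

        b, a = sps.butter(4, 10.0, btype="highpass", fs=FS)
        freqs = np.array([1.0, 5.0, 20.0, 50.0])
        _, h = sps.freqz(b, a, worN=freqs, fs=FS)
        fc = 10.0
        closed = ((freqs / fc) ** 4 / np.sqrt(1 + (freqs / fc) ** 8)) ** 2
        assert np.abs(h) ** 2 == pytest.approx(closed, rel=0.01)

    def test_cutoff_above_nyquist_rejected(self):
        w = make_window(np.zeros((1, 1000)), stage="detrended")
        with pytest.raises(ConfigError, match="Nyquist"):
            e.highpass_butterworth(w, cutoff=600.0)

    def test_low_band_energy_attenuated_for_broadband_input(self):
        """The 10 Hz cutoff is the half-power point (zero-phase energy gain
        0.25 there), so 1-10 Hz energy drops by ~2 orders overall while the
        deep stopband below 5 Hz is attenuated past 1e-4."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(8000)
        w = make_window(x, stage="detrended")
        out = e.highpass_butterworth(w)
        freqs = np.fft.rfftfreq(8000, 1 / FS)
        spec_before = np.abs(np.fft.rfft(x)) ** 2
        spec_after = np.abs(np.fft.rfft(out.samples[0])) ** 2
        band = (freqs >= 1.0) & (freqs <= 10.0)
        assert spec_after[band].sum() < 0.05 * spec_before[band].sum()
        # deep-stopband energy gain from the designed response (the DFT of a
        # finite segment hits a spectral-leakage floor well above this)
        from scipy import signal as sps

        b, a = sps.butter(4, 10.0, btype="highpass", fs=FS)
        _, h = sps.freqz(b, a, worN=np.linspace(1.0, 5.0, 50), fs=FS)
        assert (np.abs(h) ** 4).max() < 1e-4


class TestAdaptiveNotch:
    def test_no_spectral_peak_means_identity_up_to_roundtrip(self, pre_config):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 1000))
        w = make_window(x, stage="highpassed")
        out = e.adaptive_notch(w, pre_config)
        assert np.abs(out.samples - x).max() < 1e-9

    def test_50hz_peak_reduced_to_flank_level_73hz_preserved(self, pre_config):
        x = 5.0 * np.sin(2 * np.pi * 50 * T1 + 0.2) + np.sin(2 * np.pi * 73 * T1)
        w = make_window(x, stage="highpassed")
        out = e.adaptive_notch(w, pre_config)
        mags = np.abs(np.fft.rfft(out.samples[0]))
        flank = np.median(
            np.abs(np.fft.rfft(x))[[40, 41, 42, 58, 59, 60]]
        )
        assert mags[50] <= flank + 1e-9
        assert mags[73] == pytest.approx(500.0, rel=0.01)

    def test_both_harmonic_peaks_attenuated(self, pre_config):
        x = 4.0 * np.sin(2 * np.pi * 50 * T1) + 3.0 * np.sin(2 * np.pi * 150 * T1)
        w = make_window(x, stage="highpassed")
        out = e.adaptive_notch(w, pre_config)
        mags = np.abs(np.fft.rfft(out.samples[0]))
        assert mags[50] < 1e-6 * 500 * 4
        assert mags[150] < 1e-6 * 500 * 3

    def test_output_is_real_and_stage_advances(self, pre_config):
        w = make_window(np.sin(2 * np.pi * 50 * T1), stage="highpassed")
        out = e.adaptive_notch(w, pre_config)
        assert out.samples.dtype.kind == "f"
        assert out.stage == "notched"


class TestRejectAbnormal:
    def test_boundary_amplitudes(self):
        near = make_window(np.full((6, 1000), 1999.0), stage="notched")
        over = make_window(np.zeros((6, 1000)), stage="notched")
        over.samples[2, 500] = 2001.0
        kept, dropped = e.reject_abnormal([near, over])
        assert kept == [near] and dropped == [over]

    def test_empty_input_gives_empty_partition(self):
        assert e.reject_abnormal([]) == ([], [])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_preserves_windows_and_values(self, seed):
        rng = np.random.default_rng(seed)
        windows = [
            make_window(rng.normal(0, 1200, (2, 100)), stage="notched")
            for _ in range(6)
        ]
        snapshots = [w.samples.copy() for w in windows]
        kept, dropped = e.reject_abnormal(windows)
        assert sorted(map(id, kept + dropped)) == sorted(map(id, windows))
        for w, snap in zip(windows, snapshots):
            assert np.array_equal(w.samples, snap)


class TestPipeline:
    def test_clean_recording_keeps_all_windows(self):
        cfg = silent_config(class_band_profiles={"no": np.full(13, 300.0)}, seed=4)
        rec = e.generate_recording(cfg, "P1", 1, "no", 8)
        kept = e.preprocess_pipeline(rec)
        assert len(kept) == 8
        assert all(w.stage == "notched" for w in kept)

    def test_single_burst_rejects_exactly_one_window(self):
        cfg = silent_config(
            class_band_profiles={"no": np.full(13, 300.0)}, outlier_prob=1.0, seed=4
        )
        rec = e.generate_recording(cfg, "P1", 1, "no", 8)
        kept = e.preprocess_pipeline(rec)
        assert len(kept) == 7

    def test_drift_and_powerline_only_leave_sub_microvolt_residual(self):
        cfg = silent_config(drift_coeff_scale=300.0, powerline_amp=20.0,
                            powerline_harmonics=3, seed=1)
        rec = e.generate_recording(cfg, "P1", 1, "no", 42)
        kept = e.preprocess_pipeline(rec)
        assert len(kept) == 8
        assert all(np.sqrt(np.mean(w.samples**2)) < 1.0 for w in kept)

    def test_pipeline_nearly_idempotent_and_notch_exactly_so(self, pre_config):
        """Re-running the chain on its own output is a no-op up to the
        detrender's small polynomial projection of oscillatory content
        (~1-2% of peak amplitude); the notch stage alone is exactly
        idempotent."""
        x = (
            80.0 * np.sin(2 * np.pi * 73 * T1 + 0.3)
            + 40.0 * np.sin(2 * np.pi * 211 * T1 + 1.0)
            + 20.0 * np.sin(2 * np.pi * 307 * T1 + 2.0)
        )
        w = make_window(np.tile(x, (6, 1)))
        once = e.adaptive_notch(
            e.highpass_butterworth(e.detrend_poly(w)), pre_config
        )
        again = e.adaptive_notch(
            e.highpass_butterworth(e.detrend_poly(replace(once, stage="raw"))),
            pre_config,
        )
        peak = np.abs(once.samples).max()
        assert np.abs(again.samples - once.samples).max() < 0.02 * peak
        twice_notched = e.adaptive_notch(replace(once, stage="highpassed"), pre_config)
        assert np.abs(twice_notched.samples - once.samples).max() < 1e-9
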