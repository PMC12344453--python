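import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonosync import (PSOptions, Signal, instantaneous_phase, pointwise_ps,
                       windowed_ps)

from conftest import FS, sine


class TestInstantaneousPhase:
    def test_cosine_phase_advance(self):
        f = 100.0
        s = Signal(np.cos(2 * np.pi * f * np.arange(int(FS)) / FS), fs=FS)
        phi = np.unwrap(instantaneous_phase(s))
        interior = slice(int(0.1 * FS), int(0.9 * FS))
        dphi = np.diff(phi[interior])
        assert np.max(np.abs(dphi - 2 * np.pi * f / FS)) < 1e-3

    def test_sine_lags_cosine_by_quarter_period(self):
        t = np.arange(int(FS)) / FS
        c = Signal(np.cos(2 * np.pi * 100 * t), fs=FS)
        s = Signal(np.sin(2 * np.pi * 100 * t), fs=FS)
        diff = instantaneous_phase(c) - instantaneous_phase(s)
        diff = np.angle(np.exp(1j * diff))  # wrap
        interior = slice(int(0.1 * FS), int(0.9 * FS))
        np.testing.assert_allclose(diff[interior], np.pi / 2, atol=1e-3)

    def test_slow_envelope_leaves_phase_unchanged(self):
        """Bedrosian condition: a slow AM envelope does not move the phase."""
        t = np.arange(int(FS)) / FS
        carrier = np.cos(2 * np.pi * 100 * t)
        env = 1.0 + 0.3 * np.cos(2 * np.pi * 2 * t)
        p_plain = instantaneous_phase(Signal(carrier, fs=FS))
        p_am = instantaneous_phase(Signal(env * carrier, fs=FS))
        diff = np.angle(np.exp(1j * (p_am - p_plain)))
        interior = slice(int(0.1 * FS), int(0.9 * FS))
        assert np.max(np.abs(diff[interior])) < 1e-2

    def test_zero_signal_raises(self):
        with pytest.raises(ValueError):
            instantaneous_phase(Signal(np.zeros(100), fs=FS))


class TestPointwisePS:
    def test_identical_signals_give_one(self):
        s = sine(120.0)
        ps = pointwise_ps(s, s)
        np.testing.assert_allclose(ps, 1.0, atol=1e-12)

    def test_bounds_and_symmetry(self):
        a, b = sine(100.0), sine(161.8)
        ps_ab = pointwise_ps(a, b)
        ps_ba = pointwise_ps(b, a)
        assert np.all(ps_ab <= 1.0) and np.all(ps_ab >= -1.0)
        np.testing.assert_array_equal(ps_ab, ps_ba)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pointwise_ps(sine(100.0, 1.0), sine(100.0, 0.5))


class TestWindowRule:
    def test_group2_nwin_1000(self):
        opts = PSOptions.group2(fs=20_000.0)
        assert opts.nwin == 1000

    def test_group1_nwin_floor(self):
        """fo_iEGG = fo_audio = 68 Hz: fo_min = 13.6 Hz, Nwin = floor(20000/13.6)."""
        opts = PSOptions.group1(fs=20_000.0, fo_iegg=68.0, fo_audio=68.0)
        assert opts.fo_min == pytest.approx(13.6)
        assert opts.nwin == 1470

    def test_invalid_options(self):
        with pytest.raises(ValueError):
            PSOptions(fs=20_000.0, fo_min=-1.0)
        with pytest.raises(ValueError):
            PSOptions(fs=20_000.0, fo_min=20.0, bandpass=(500.0, 100.0))


class TestWindowedPS:
    def test_in_phase_median_one(self):
        s = sine(120.0, 2.0)
        series = windowed_ps(s, s, PSOptions.group2(FS)).interior()
        np.testing.assert_allclose(series.median, 1.0, atol=0.02)

    def test_antiphase_median_minus_one(self):
        t = np.arange(int(2 * FS)) / FS
        a = Signal(np.sin(2 * np.pi * 100 * t), fs=FS)
        b = Signal(np.sin(2 * np.pi * 100 * (t - 0.005)), fs=FS)  # half period
        series = windowed_ps(a, b, PSOptions.group2(FS)).interior()
        np.testing.assert_allclose(series.median, -1.0, atol=0.02)

    def test_quadrature_median_and_iqr_zero(self):
        t = np.arange(int(2 * FS)) / FS
        a = Signal(np.sin(2 * np.pi * 100 * t), fs=FS)
        b = Signal(np.cos(2 * np.pi * 100 * t), fs=FS)
        series = windowed_ps(a, b, PSOptions.group2(FS)).interior()
        assert np.all(np.abs(series.median) < 0.02)
        assert np.all(series.iqr < 0.02)

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_integer_ratio_median_near_zero(self, n):
        """n:1 sinusoid pairs: windows spanning whole base periods have
        median PS within 0.05 of zero."""
        base = 80.0
        a, b = sine(base, 2.0), sine(n * base, 2.0)
        series = windowed_ps(a, b, PSOptions.group2(FS)).interior()
        assert np.all(np.abs(series.median) < 0.05)

    def test_symmetry_exact(self):
        a, b = sine(100.0, 2.0), sine(161.8, 2.0)
        opts = PSOptions.group2(FS)
        sab = windowed_ps(a, b, opts)
        sba = windowed_ps(b, a, opts)
        np.testing.assert_array_equal(sab.median, sba.median)
        np.testing.assert_array_equal(sab.q25, sba.q25)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_amplitude_invariance(self, ka, kb):
        t = np.arange(4000) / FS
        xa = np.sin(2 * np.pi * 100 * t)
        xb = np.sin(2 * np.pi * 200 * t + 0.3)
        ps1 = pointwise_ps(Signal(xa, fs=FS), Signal(xb, fs=FS))
        ps2 = pointwise_ps(Signal(ka * xa, fs=FS), Signal(kb * xb, fs=FS))
        np.testing.assert_allclose(ps1, ps2, atol=1e-9)

    def test_quantile_ordering_invariant(self):
        rng = np.random.default_rng(0)
        a = Signal(rng.normal(size=int(2 * FS)), fs=FS)
        b = Signal(rng.normal(size=int(2 * FS)), fs=FS)
        series = windowed_ps(a, b, PSOptions.group2(FS))
        m = series.valid
        assert np.all(series.q25[m] <= series.median[m] + 1e-12)
        assert np.all(series.median[m] <= series.q75[m] + 1e-12)
        assert np.all(series.median[m] >= -1.0) and np.all(series.median[m] <= 1.0)

    def test_silent_window_reported_missing(self):
        """Where one channel is silent the PS window is missing, not zero."""
        t = np.arange(int(2 * FS)) / FS
        a = Signal(np.sin(2 * np.pi * 100 * t), fs=FS)
        xb = np.sin(2 * np.pi * 100 * t)
        xb[: int(FS)] = 0.0  # SAW absent during the first second
        b = Signal(xb, fs=FS)
        series = windowed_ps(a, b, PSOptions.group2(FS))
        first_half = series.t_center < 0.95
        second_half = (series.t_center > 1.05) & (series.t_center < 1.9)
        assert np.all(~series.valid[first_half])
        assert np.all(series.valid[second_half])

    def test_window_longer_than_signal_raises(self):
        s = sine(100.0, 0.01)
        with pytest.raises(ValueError):
            windowed_ps(s, s, PSOptions.group2(FS))

    def test_bandpass_path_preserves_in_phase(self):
        s = sine(120.0, 2.0)
        opts = PSOptions.group2(FS, bandpass=(40.0, 500.0))
        series = windowed_ps(s, s, opts).interior()
        np.testing.assert_allclose(series.median, 1.0, atol=0.02)

    def test_filter_ps_series_flag(self):
        s = sine(120.0, 2.0)
        opts = PSOptions.group2(FS, bandpass=(40.0, 500.0), filter_ps_series=True)
        series = windowed_ps(s, s, opts).interior()
        np.testing.assert_allclose(series.median, 1.0, atol=0.05)
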