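import numpy as np
import pytest

from phonosync import (CouplingSpec, FoTrajectory, OscillatorSpec, RenderSpec,
                       SceneSpec, Signal, add_noise, make_coupled_scene,
                       render_frames)
from phonosync.synth import region_capacities

from conftest import FS, locked_scene


def dft_peak_hz(x: np.ndarray, fs: float) -> float:
    x = x - x.mean()
    mag = np.abs(np.fft.rfft(x))
    return float(np.argmax(mag) * fs / x.size)


def autocorr(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    nfft = 1 << int(np.ceil(np.log2(2 * x.size)))
    ac = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2, nfft)[: x.size]
    return ac / ac[0]


class TestGroundTruth:
    def test_locked_ratio_two_supraglottic_fo(self):
        rec, gt = make_coupled_scene(locked_scene(fo=136.0, n=2))
        np.testing.assert_allclose(gt.fo_supraglottic, 68.0)
        np.testing.assert_allclose(gt.ratio, 2.0)

    def test_locked_one_to_one_same_dominant_peak(self):
        rec, _ = make_coupled_scene(locked_scene(fo=120.0, n=1))
        f_iegg = dft_peak_hz(rec["iEGG"].samples, FS)
        f_saw = dft_peak_hz(rec["SAW"].samples, FS)
        assert f_iegg == pytest.approx(f_saw, abs=FS / len(rec["iEGG"]))

    def test_spectral_ground_truth_within_one_bin(self):
        """Locked, noiseless: SAW DFT peak within one bin of true fo/n."""
        for n in (2, 3, 5):
            rec, gt = make_coupled_scene(locked_scene(fo=210.0, n=n, duration=2.0))
            bin_hz = FS / len(rec["SAW"])
            assert dft_peak_hz(rec["SAW"].samples, FS) == pytest.approx(
                210.0 / n, abs=bin_hz)

    def test_ratio_conservation_through_glissando(self):
        spec = SceneSpec(
            glottal=OscillatorSpec(fo=FoTrajectory.glissando(150, 240, 0.3, 1.2)),
            coupling=CouplingSpec(ratio_n=3), duration=1.5, fs=FS)
        _, gt = make_coupled_scene(spec)
        np.testing.assert_allclose(gt.ratio, 3.0)


class TestDeterminismAndEvents:
    def test_bit_identical_given_seed(self):
        spec = locked_scene(seed=7, snr_db=20.0, regime="chaotic")
        rec1, _ = make_coupled_scene(spec)
        rec2, _ = make_coupled_scene(locked_scene(seed=7, snr_db=20.0,
                                                  regime="chaotic"))
        for lab in rec1.channels:
            np.testing.assert_array_equal(rec1[lab].samples, rec2[lab].samples)

    def test_event_outside_duration_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(glottal=OscillatorSpec(fo=FoTrajectory.constant(100.0)),
                      duration=1.0, events=[{"time": 2.0, "kind": "frequency_jump",
                                             "to_hz": 120.0}])

    def test_unsorted_events_rejected(self):
        evs = [{"time": 0.8, "kind": "frequency_jump", "to_hz": 120.0},
               {"time": 0.2, "kind": "frequency_jump", "to_hz": 110.0}]
        with pytest.raises(ValueError):
            SceneSpec(glottal=OscillatorSpec(fo=FoTrajectory.constant(100.0)),
                      duration=1.0, events=evs)

    def test_frequency_jump_event_changes_ground_truth(self):
        spec = SceneSpec(glottal=OscillatorSpec(fo=FoTrajectory.constant(128.0)),
                         duration=1.0, fs=FS,
                         events=[{"time": 0.5, "kind": "frequency_jump",
                                  "to_hz": 137.0}])
        _, gt = make_coupled_scene(spec)
        assert gt.fo_glottal[0] == 128.0
        assert gt.fo_glottal[-1] == 137.0


class TestChaoticRegime:
    def test_chaotic_autocorrelation_below_half(self):
        """Aperiodic check: SAW autocorrelation < 0.5 at all lags >= 1 period."""
        rec, gt = make_coupled_scene(locked_scene(fo=136.0, n=2, duration=2.0,
                                                  regime="chaotic", seed=3))
        ac = autocorr(rec["SAW"].samples)
        period = int(round(FS / 68.0))
        assert ac[period: ac.size // 2].max() < 0.5


class TestAddNoise:
    def test_infinite_snr_is_identity(self):
        s = Signal(np.sin(np.linspace(0, 20, 1000)), fs=100.0)
        out = add_noise(s, None, seed=0)
        np.testing.assert_array_equal(out.samples, s.samples)
        out = add_noise(s, np.inf, seed=0)
        np.testing.assert_array_equal(out.samples, s.samples)

    def test_zero_db_noise_power(self):
        """Unit-power sinusoid at 0 dB: added noise power within 5% of 1."""
        fs = 20_000.0
        t = np.arange(100_000) / fs
        s = Signal(np.sqrt(2) * np.sin(2 * np.pi * 100 * t), fs=fs)
        noisy = add_noise(s, 0.0, seed=11)
        noise_power = np.var(noisy.samples - s.samples)
        assert noise_power == pytest.approx(np.mean(s.samples**2), rel=0.05)

    def test_same_seed_identical(self):
        s = Signal(np.ones(100), fs=10.0)
        a = add_noise(s, 10.0, seed=5)
        b = add_noise(s, 10.0, seed=5)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_zero_power_error(self):
        with pytest.raises(ValueError):
            add_noise(Signal(np.zeros(10), fs=10.0), 10.0)


class TestRenderFrames:
    def test_constant_area_exact_pixel_count(self):
        """Requested 500 px² glottal area renders exactly 500 bright pixels."""
        render = RenderSpec()
        stack, true = render_frames(np.full(5, 500.0), np.zeros(5), render)
        level = render.brightness["glottal"]
        for frame in stack.frames:
            assert int((frame == level).sum()) == 500
        np.testing.assert_array_equal(true["glottal"], 500.0)

    def test_zero_areas_give_uniform_background(self):
        render = RenderSpec()
        stack, _ = render_frames(np.zeros(3), np.zeros(3), render)
        assert np.all(stack.frames == render.brightness["background"])

    def test_sinusoidal_area_rms_within_two_percent(self):
        render = RenderSpec()
        req = 500 + 500 * np.sin(2 * np.pi * np.arange(50) / 25)  # 0..1000 px²
        stack, _ = render_frames(req, np.zeros(50), render)
        level = render.brightness["glottal"]
        rendered = (stack.frames == level).sum(axis=(1, 2)).astype(float)
        big = req >= 100
        rms = np.sqrt(np.mean((rendered[big] - req[big]) ** 2))
        assert rms / req[big].mean() < 0.02

    def test_capacity_exceeded_raises(self):
        render = RenderSpec()
        cap_g, _ = region_capacities(render)
        with pytest.raises(ValueError):
            render_frames(np.array([cap_g + 10.0]), np.zeros(1), render)

    def test_supraglottic_annulus_excludes_glottal_region(self):
        render = RenderSpec()
        stack, _ = render_frames(np.full(2, 1000.0), np.full(2, 5000.0), render)
        b = render.brightness
        n_g = (stack.frames[0] == b["glottal"]).sum()
        n_s = (stack.frames[0] == b["supraglottic"]).sum()
        assert n_g == 1000 and n_s == 5000
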