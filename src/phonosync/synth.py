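"""Synthetic coupled glottal/supraglottic phonation scenes with ground truth.

The generator emulates two coupled quasi-periodic oscillators: the vocal
folds (glottal source, ~44–280 Hz) and a supraglottic structure (ventricular
folds or similar) oscillating at an integer fraction fo/n of the glottal
frequency when entrained.  Regimes:

``locked``
    The supraglottic phase is rigidly derived from the glottal phase
    (φ_s = φ_g / n + offset), so the n:1 ratio holds exactly even through
    glissandi and frequency jumps.
``drifting``
    The supraglottic oscillator runs near fo/n but with a slow sinusoidal
    detune, so the ratio wanders around n without hard locking.
``biphonation``
    The supraglottic frequency is an irrational multiple (golden-ratio
    scaled) of the glottal frequency — two incommensurate sources.
``chaotic``
    Supraglottic cycle lengths are jittered cycle-by-cycle by a logistic map
    at r = 4 (±20 % of the nominal period), with successive map iterates
    also driving the cycle amplitude and pulse width — a reproducible,
    seedable source of aperiodicity in timing, level and shape.

Channels produced (all at one rate, 20 kHz by default):

* ``GAW``   — glottal area waveform (non-negative pulse train),
* ``SAW``   — supraglottic area waveform,
* ``iEGG``  — glottal waveform with alternating-cycle amplitude modulation
  by supraglottic contact (period-doubling signature, depth configurable),
* ``audio`` — weighted mix of the modulated glottal waveform and the
  derivative of the supraglottic waveform, plus optional noise.

Frames: a central glottal ellipse and a surrounding supraglottic annulus
whose *pixel areas* track the two waveforms exactly (pixels are switched on
in order of elliptical radius, so the rendered area equals the requested
area to rounding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import FrameStack, Recording, Signal

GOLDEN = (1 + math.sqrt(5)) / 2

REGIMES = ("locked", "drifting", "biphonation", "chaotic")
PULSE_SHAPES = ("impulse_train", "raised_cosine_pulse", "sinusoid")


# ---------------------------------------------------------------------------
# fo trajectories


@dataclass
class FoTrajectory:
    """Piecewise-linear fo(t) with optional discontinuities.

    ``breakpoints`` is a sorted list of ``(t, f_left, f_right)``: the value
    approaching ``t`` from below is ``f_left``, from ``t`` onward the
    trajectory restarts at ``f_right`` and interpolates linearly to the next
    breakpoint.  Constructors cover the three cases used in practice.
    """

    breakpoints: list[tuple[float, float, float]]

    @classmethod
    def constant(cls, fo: float) -> "FoTrajectory":
        return cls([(0.0, fo, fo)])

    @classmethod
    def glissando(cls, f_start: float, f_end: float, t_start: float,
                  t_end: float) -> "FoTrajectory":
        """Hold f_start, glide linearly over [t_start, t_end], hold f_end."""
        return cls([(0.0, f_start, f_start), (t_start, f_start, f_start),
                    (t_end, f_end, f_end)])

    @classmethod
    def step(cls, f_before: float, f_after: float, t_jump: float) -> "FoTrajectory":
        return cls([(0.0, f_before, f_before), (t_jump, f_before, f_after)])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        bps = sorted(self.breakpoints)
        out = np.empty_like(t)
        for i, (ti, _fl, fr) in enumerate(bps):
            if i + 1 < len(bps):
                tj, fl_next, _ = bps[i + 1]
                mask = (t >= ti) & (t < tj)
                span = max(tj - ti, 1e-12)
                out[mask] = fr + (fl_next - fr) * (t[mask] - ti) / span
            else:
                out[t >= ti] = fr
        out[t < bps[0][0]] = bps[0][1]
        if np.any(out <= 0):
            raise ValueError("fo trajectory must be positive everywhere")
        return out


@dataclass
class OscillatorSpec:
    """One quasi-periodic pulse-train oscillator."""

    fo: FoTrajectory
    pulse_shape: str = "raised_cosine_pulse"
    open_quotient: float = 0.6
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.pulse_shape not in PULSE_SHAPES:
            raise ValueError(f"pulse_shape must be one of {PULSE_SHAPES}")
        if not 0 < self.open_quotient <= 1:
            raise ValueError("open_quotient must be in (0, 1]")


@dataclass
class CouplingSpec:
    """How the supraglottic oscillator relates to the glottal one."""

    ratio_n: int = 2              # glottal cycles per supraglottic cycle
    phase_offset: float = 0.0     # radians, supraglottic cycle phase
    regime: str = "locked"
    subharmonic_depth: float = 0.0  # alternating-cycle amplitude reduction
    noise_snr_db: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_n < 1:
            raise ValueError("ratio_n must be >= 1")
        if not 0 <= self.subharmonic_depth <= 1:
            raise ValueError("subharmonic_depth must be in [0, 1]")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")


@dataclass
class RenderSpec:
    """Geometry and brightness of rendered endoscopy-like frames.

    Default frame geometry matches a high-speed laryngoscopy setup:
    386×320 px at 20 000 fps, greyscale.  The glottal region is a central
    ellipse (aspect ``glottal_aspect`` height:width), the supraglottic region
    an annulus around it; each region's pixel area follows its waveform.
    Brightness defaults to background < supraglottic < glottal; any distinct
    ordering is allowed (endoscopic images often show the glottis dark).
    """

    frame_shape: tuple[int, int] = (320, 386)   # (height, width)
    fps: float = 20_000.0
    center: tuple[float, float] | None = None   # (row, col); default frame centre
    glottal_aspect: float = 3.0
    annulus_inner_px2: float = 4000.0           # fixed hole clearing the glottal region
    brightness: dict = field(default_factory=lambda: {
        "background": 0.10, "supraglottic": 0.55, "glottal": 0.90})
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        b = self.brightness
        if len({round(v, 6) for v in b.values()}) != 3:
            raise ValueError("brightness levels must be distinct")


@dataclass
class SceneSpec:
    """Full parametric description of a synthetic phonation scene."""

    glottal: OscillatorSpec
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    supraglottic: OscillatorSpec | None = None  # derived from ratio when None
    duration: float = 2.0
    fs: float = 20_000.0
    events: list[dict] = field(default_factory=list)
    render: RenderSpec | None = None
    audio_weights: tuple[float, float] = (0.7, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        times = [e.get("time", 0.0) for e in self.events]
        if any(t < 0 or t > self.duration for t in times):
            raise ValueError("events must lie within [0, duration]")
        if times != sorted(times):
            raise ValueError("events must be sorted by time")
        if self.render is not None and self.render.fps != self.fs:
            raise ValueError("render fps must equal signal fs (frame = sample)")


@dataclass
class GroundTruth:
    """True trajectories underlying a generated scene."""

    times: np.ndarray
    fo_glottal: np.ndarray
    fo_supraglottic: np.ndarray
    ratio: np.ndarray            # fo_glottal / fo_supraglottic, per sample
    events: list[dict]
    phase_offset: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.times,
            "fo_glottal": self.fo_glottal,
            "fo_supraglottic": self.fo_supraglottic,
            "ratio": self.ratio,
        })
        df["event"] = ""
        for ev in self.events:
            i = int(np.argmin(np.abs(self.times - ev.get("time", 0.0))))
            df.loc[i, "event"] = ev.get("kind", "")
        return df


# ---------------------------------------------------------------------------
# waveform primitives


def _wave_from_phase(phase: np.ndarray, shape: str, open_quotient: float,
                     amplitude: float) -> np.ndarray:
    """Non-negative area-like waveform as a function of accumulated phase."""
    frac = (phase / (2 * np.pi)) % 1.0
    if shape == "raised_cosine_pulse":
        w = np.where(frac < open_quotient,
                     0.5 * (1 - np.cos(2 * np.pi * frac / open_quotient)), 0.0)
    elif shape == "sinusoid":
        w = 0.5 * (1 + np.sin(phase))
    elif shape == "impulse_train":
        w = (np.diff(np.floor(phase / (2 * np.pi)), prepend=phase[0] // (2 * np.pi))
             > 0).astype(float)
    else:  # pragma: no cover - guarded by OscillatorSpec
        raise ValueError(shape)
    return amplitude * w


def add_noise(s: Signal, snr_db: float | None, seed: int | np.random.Generator = 0) -> Signal:
    """Additive white Gaussian noise at a requested SNR (dB).

    ``snr_db=None`` or ``inf`` returns an identical copy.  Deterministic for
    a given seed.
    """
    if snr_db is None or np.isinf(snr_db):
        return Signal(s.samples.copy(), fs=s.fs, t0=s.t0, label=s.label)
    power = float(np.mean(s.samples**2))
    if power == 0.0:
        raise ValueError("cannot set a finite SNR on a zero-power signal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = math.sqrt(power / 10 ** (snr_db / 10))
    noisy = s.samples + rng.normal(0.0, sigma, size=len(s))
    return Signal(noisy, fs=s.fs, t0=s.t0, label=s.label)


# ---------------------------------------------------------------------------
# scene assembly


def _apply_events(fo: np.ndarray, t: np.ndarray, events: Sequence[dict],
                  fs: float) -> tuple[np.ndarray, str | None, float]:
    """Fold declarative events into the glottal fo array.

    Supported kinds: ``frequency_jump {to_hz}``, ``glissando_start
    {to_hz, duration}``, ``regime_switch {regime}`` (returned, applied by
    caller).  Returns (fo, switched_regime, switch_time).
    """
    fo = fo.copy()
    regime_switch = None
    switch_time = np.inf
    for ev in events:
        kind = ev.get("kind")
        te = float(ev.get("time", 0.0))
        i0 = int(round(te * fs))
        if kind == "frequency_jump":
            fo[i0:] = float(ev["to_hz"])
        elif kind == "glissando_start":
            dur = float(ev["duration"])
            i1 = min(fo.size, i0 + int(round(dur * fs)))
            f_from = fo[i0] if i0 < fo.size else fo[-1]
            ramp = np.linspace(f_from, float(ev["to_hz"]), max(i1 - i0, 1))
            fo[i0:i1] = ramp[: max(i1 - i0, 0)]
            fo[i1:] = float(ev["to_hz"])
        elif kind == "regime_switch":
            regime_switch = str(ev["regime"])
            switch_time = te
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    return fo, regime_switch, switch_time


def _chaotic_phase(n: int, fs: float, base_fo: np.ndarray,
                   rng: np.random.Generator, jitter: float = 0.2
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Supraglottic phase with cycle lengths and amplitudes driven by a
    logistic map at r = 4.

    Each cycle's frequency is ``base_fo · (1 + jitter·(2x_k − 1))`` (±20 %
    cycle-length jitter by default) where ``x_{k+1} = 4 x_k (1 − x_k)``,
    seeded away from the map's unstable fixed points.  Successive map
    iterates set the cycle amplitude in (0, 1) and a cycle-shape (pulse
    width) factor: chaotic phonation varies amplitude and pulse shape as
    well as period, with near-silent cycles interspersed.  Returns
    (phase, fo, amplitude, width_factor) per sample.
    """
    x = float(rng.uniform(0.05, 0.45))
    phase = np.empty(n)
    fo_out = np.empty(n)
    amp = np.empty(n)
    width = np.empty(n)
    phi = 0.0
    i = 0
    while i < n:
        x = 4.0 * x * (1.0 - x)
        x = min(max(x, 1e-9), 1 - 1e-9)
        factor = 1.0 + jitter * (2.0 * x - 1.0)
        x = 4.0 * x * (1.0 - x)
        x = min(max(x, 1e-9), 1 - 1e-9)
        a_cyc = x
        x = 4.0 * x * (1.0 - x)
        x = min(max(x, 1e-9), 1 - 1e-9)
        w_cyc = 0.5 + 0.5 * x        # pulse-width multiplier in (0.5, 1)
        f_cyc = base_fo[i] * factor
        n_cyc = max(1, int(round(fs / f_cyc)))
        j = min(n, i + n_cyc)
        seg = np.arange(j - i)
        phase[i:j] = phi + 2 * np.pi * f_cyc * seg / fs
        fo_out[i:j] = f_cyc
        amp[i:j] = a_cyc
        width[i:j] = w_cyc
        phi = phi + 2 * np.pi * f_cyc * (j - i) / fs
        i = j
    return phase, fo_out, amp, width


def make_coupled_scene(spec: SceneSpec) -> tuple[Recording, GroundTruth]:
    """Generate aligned channels and ground truth for a coupled scene.

    Deterministic given ``spec.seed``: identical specs produce bit-identical
    channels.  Frames are rendered only when ``spec.render`` is set (at the
    signal rate, frame = sample).
    """
    fs = spec.fs
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)

    fo_g = spec.glottal.fo(t)
    fo_g, regime_switch, switch_time = _apply_events(fo_g, t, spec.events, fs)
    phase_g = 2 * np.pi * np.cumsum(fo_g) / fs

    coup = spec.coupling
    regime = coup.regime
    n_ratio = coup.ratio_n
    supra_amp = None    # per-cycle amplitude modulation (chaotic regime only)
    supra_width = None  # per-cycle pulse-width modulation (chaotic regime only)

    if spec.supraglottic is not None:
        fo_s = spec.supraglottic.fo(t)
        phase_s = 2 * np.pi * np.cumsum(fo_s) / fs + coup.phase_offset
        sup_spec = spec.supraglottic
    else:
        sup_spec = OscillatorSpec(fo=spec.glottal.fo,
                                  pulse_shape=spec.glottal.pulse_shape,
                                  open_quotient=min(1.0, spec.glottal.open_quotient * 1.2),
                                  amplitude=spec.glottal.amplitude)
        if regime == "locked":
            phase_s = phase_g / n_ratio + coup.phase_offset
            fo_s = fo_g / n_ratio
        elif regime == "drifting":
            detune = 1.0 + 0.02 * np.sin(2 * np.pi * 0.7 * t)
            fo_s = fo_g / n_ratio * detune
            phase_s = 2 * np.pi * np.cumsum(fo_s) / fs + coup.phase_offset
        elif regime == "biphonation":
            fo_s = fo_g * (GOLDEN - 1) / n_ratio  # irrational multiple
            phase_s = 2 * np.pi * np.cumsum(fo_s) / fs + coup.phase_offset
        elif regime == "chaotic":
            phase_s, fo_s, supra_amp, supra_width = _chaotic_phase(
                n, fs, fo_g / n_ratio, rng)
            phase_s = phase_s + coup.phase_offset
        else:  # pragma: no cover
            raise ValueError(regime)
        if regime_switch is not None:
            # the switched regime applies from switch_time on: regenerate the
            # tail of the supraglottic phase, continuous at the splice point
            i0 = int(round(switch_time * fs))
            phi0 = phase_s[i0 - 1] if i0 > 0 else 0.0
            if regime_switch == "chaotic":
                ph_tail, fo_tail, amp_tail, w_tail = _chaotic_phase(
                    n - i0, fs, fo_g[i0:] / n_ratio,
                    np.random.default_rng(spec.seed + 1))
                base_amp = supra_amp if supra_amp is not None else np.ones(n)
                base_w = supra_width if supra_width is not None else np.ones(n)
                supra_amp = np.concatenate([base_amp[:i0], amp_tail])
                supra_width = np.concatenate([base_w[:i0], w_tail])
            elif regime_switch == "biphonation":
                fo_tail = fo_g[i0:] * (GOLDEN - 1) / n_ratio
                ph_tail = np.cumsum(fo_tail) * 2 * np.pi / fs
            elif regime_switch == "locked":
                ph_tail = (phase_g[i0:] - phase_g[i0]) / n_ratio
                fo_tail = fo_g[i0:] / n_ratio
            else:
                raise ValueError(f"unsupported regime_switch {regime_switch!r}")
            phase_s = np.concatenate([phase_s[:i0], phi0 + ph_tail])
            fo_s = np.concatenate([fo_s[:i0], fo_tail])

    glottal_wave = _wave_from_phase(phase_g, spec.glottal.pulse_shape,
                                    spec.glottal.open_quotient, spec.glottal.amplitude)
    sup_oq = sup_spec.open_quotient
    if supra_width is not None:
        sup_oq = np.minimum(1.0, sup_oq * supra_width)
    supra_wave = _wave_from_phase(phase_s, sup_spec.pulse_shape,
                                  sup_oq, sup_spec.amplitude)
    if supra_amp is not None:
        supra_wave = supra_wave * supra_amp

    # period-doubling signature: supraglottic contact damps every other
    # glottal pulse (alternating-cycle amplitude modulation)
    cycle_idx = np.floor(phase_g / (2 * np.pi)).astype(int)
    mod = 1.0 - coup.subharmonic_depth * (cycle_idx % 2)
    glottal_mod = glottal_wave * mod

    w_g, w_s = spec.audio_weights
    supra_deriv = np.gradient(supra_wave) * fs
    peak = np.max(np.abs(supra_deriv))
    if peak > 0:
        supra_deriv = supra_deriv / peak
    audio = w_g * glottal_mod + w_s * supra_deriv

    channels = {
        "GAW": Signal(glottal_wave, fs=fs, label="GAW"),
        "SAW": Signal(supra_wave, fs=fs, label="SAW"),
        "iEGG": Signal(glottal_mod, fs=fs, label="iEGG"),
        "audio": Signal(audio, fs=fs, label="audio"),
    }
    if coup.noise_snr_db is not None:
        channels = {lab: add_noise(s, coup.noise_snr_db, rng)
                    for lab, s in channels.items()}

    frames = None
    if spec.render is not None:
        cap_g, cap_s = region_capacities(spec.render)
        g_area = glottal_wave / max(glottal_wave.max(), 1e-12) * 0.8 * cap_g
        s_area = supra_wave / max(supra_wave.max(), 1e-12) * 0.8 * cap_s
        frames, _true = render_frames(g_area, s_area, spec.render)

    rec = Recording(channels=channels, frames=frames)
    gt = GroundTruth(times=t, fo_glottal=fo_g, fo_supraglottic=fo_s,
                     ratio=fo_g / fo_s, events=list(spec.events),
                     phase_offset=coup.phase_offset)
    return rec, gt


# ---------------------------------------------------------------------------
# frame rendering


def _region_orders(render: RenderSpec) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Flat pixel indices of the glottal / supraglottic regions, sorted by
    elliptical radius, so that switching on the first k pixels renders a
    region of exactly k px²."""
    h, w = render.frame_shape
    cr, cc = render.center if render.center is not None else ((h - 1) / 2, (w - 1) / 2)
    rows, cols = np.mgrid[0:h, 0:w]
    # small irrational offset avoids radius ties on the integer grid
    dr = (rows - cr - 0.017) / render.glottal_aspect
    dc = cols - cc - 0.013
    r2 = (dr**2 + dc**2).ravel()
    order = np.argsort(r2, kind="stable")
    inner_n = int(render.annulus_inner_px2)
    glottal_order = order  # central pixels first
    annulus_order = order[inner_n:]  # pixels outside the fixed inner hole
    return glottal_order, annulus_order, (h, w)


def region_capacities(render: RenderSpec) -> tuple[int, int]:
    """Maximum renderable glottal and supraglottic areas in px²."""
    g_order, a_order, _ = _region_orders(render)
    return int(render.annulus_inner_px2), int(a_order.size)


def render_frames(glottal_area_px2: np.ndarray, supraglottic_area_px2: np.ndarray,
                  render: RenderSpec) -> tuple[FrameStack, dict[str, np.ndarray]]:
    """Render frames whose region pixel areas follow the two waveforms.

    Returns the stack and the per-frame *true* pixel areas actually rendered
    (equal to the rounded requested areas).  Raises when a requested area
    exceeds the region capacity.
    """
    g = np.asarray(glottal_area_px2, dtype=float)
    s = np.asarray(supraglottic_area_px2, dtype=float)
    if g.shape != s.shape:
        raise ValueError("area waveforms must have equal length")
    if np.any(g < 0) or np.any(s < 0):
        raise ValueError("areas must be non-negative")
    g_order, a_order, (h, w) = _region_orders(render)
    cap_g, cap_s = int(render.annulus_inner_px2), int(a_order.size)
    g_px = np.round(g).astype(int)
    s_px = np.round(s).astype(int)
    if g_px.max(initial=0) > cap_g:
        raise ValueError(f"glottal area {g_px.max()} px² exceeds capacity {cap_g}")
    if s_px.max(initial=0) > cap_s:
        raise ValueError(f"supraglottic area {s_px.max()} px² exceeds capacity {cap_s}")

    b = render.brightness
    n = g.size
    frames = np.full((n, h * w), b["background"], dtype=float)
    for i in range(n):
        if s_px[i]:
            frames[i, a_order[: s_px[i]]] = b["supraglottic"]
        if g_px[i]:
            frames[i, g_order[: g_px[i]]] = b["glottal"]
    frames = frames.reshape(n, h, w)
    if render.rotation_deg:
        from skimage.transform import rotate
        frames = np.stack([rotate(f, render.rotation_deg, preserve_range=True)
                           for f in frames])
    stack = FrameStack(frames, fps=render.fps)
    return stack, {"glottal": g_px.astype(float), "supraglottic": s_px.astype(float)}


def ground_truth_to_csv(gt: GroundTruth, path) -> None:
    gt.to_frame().to_csv(path, index=False, float_format="%.6g")
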