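"""Fundamental-frequency tracking, spectrograms and nonlinear-phenomena
detectors.

fo tracking uses the YIN family of estimators: per frame, the difference
function d(τ) is computed (via FFT autocorrelation), normalised by its
cumulative mean (CMNDF), and the smallest lag dipping below an absolute
threshold is refined by parabolic interpolation.  Frames whose best CMNDF
stays high are flagged unvoiced.  A median filter plus an octave guard
(frames more than ~0.4 octaves from the running median are snapped back)
smooths the track; this prevents fo/2–2·fo flips on clean material.

Detectors operationalise three signatures of nonlinear phonation:

* **subharmonics** — spectral energy at fo/k (k ≥ 2) relative to the
  dominant harmonic peak, the fingerprint of period doubling;
* **frequency jumps** — step discontinuities in the fo track, separated
  from glissandi by requiring a step model to beat a linear-ramp model
  locally and the transition to complete within ``max_gap``;
* **biphonation** — two persistent narrowband components whose frequency
  ratio is not close to any small-integer ratio p/q.

All detector thresholds are package defaults tuned on synthetic material,
configurable per call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT, find_peaks, medfilt
from scipy.signal.windows import hann

from .io import Signal


@dataclass
class FoTrack:
    """Time-stamped fo estimates with per-frame voicing confidence.

    ``fo`` is NaN on unvoiced frames; ``voicing`` is 1 − min(CMNDF), a
    crude periodicity confidence in [0, 1].
    """

    times: np.ndarray
    fo: np.ndarray
    voicing: np.ndarray
    label: str = "other"
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fo = np.asarray(self.fo, dtype=float)
        self.voicing = np.asarray(self.voicing, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fo[np.isfinite(self.fo)] <= 0):
            raise ValueError("voiced fo values must be positive")

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.fo)

    def segment_stats(self, t_start: float | None = None,
                      t_end: float | None = None) -> tuple[float, float]:
        """Mean ± SD of fo over voiced frames in [t_start, t_end]."""
        m = self.voiced
        if t_start is not None:
            m &= self.times >= t_start
        if t_end is not None:
            m &= self.times <= t_end
        if not m.any():
            return (math.nan, math.nan)
        vals = self.fo[m]
        return float(vals.mean()), float(vals.std())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "fo_hz": self.fo,
                             "voicing": self.voicing})


@dataclass
class SpectrogramSpec:
    """Hann-windowed STFT parameters (window length in samples)."""

    window_length: int = 2048
    hop: int | None = None          # default window_length // 4
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.window != "hann":
            raise ValueError("only the Hann window is supported")
        if self.hop is None:
            self.hop = self.window_length // 4
        if not 0 < self.hop <= self.window_length:
            raise ValueError("hop must satisfy 0 < hop <= window_length")


@dataclass
class SpectralEvent:
    """A detected nonlinear-phonation event on a time interval."""

    kind: str                        # 'subharmonic' | 'frequency_jump' | 'biphonation'
    t_start: float
    t_end: float
    params: dict = field(default_factory=dict)
    strength: float = 0.0


# ---------------------------------------------------------------------------
# YIN fo estimation


def _frame_signal(x: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    n_frames = 1 + max(0, (x.size - frame_length) // hop)
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _yin_cmndf(frames: np.ndarray, max_lag: int) -> np.ndarray:
    """Cumulative-mean-normalised difference function per frame.

    d(τ) = Σ_{j<L} (x_j − x_{j+τ})² with integration length L = W − max_lag,
    computed with FFT cross-correlation; d'(τ) = d(τ)·τ / Σ_{u≤τ} d(u).
    """
    n_frames, W = frames.shape
    L = W - max_lag
    nfft = 1 << int(np.ceil(np.log2(2 * W)))
    fx = np.fft.rfft(frames, nfft)
    fy = np.fft.rfft(frames[:, :L][:, ::-1], nfft)
    corr = np.fft.irfft(fx * fy, nfft)[:, L - 1:L - 1 + max_lag + 1]
    sq = frames**2
    csum = np.concatenate([np.zeros((n_frames, 1)), np.cumsum(sq, axis=1)], axis=1)
    e0 = csum[:, L] - csum[:, 0]
    taus = np.arange(max_lag + 1)
    e_tau = csum[:, taus + L] - csum[:, taus]
    d = e0[:, None] + e_tau - 2 * corr
    d = np.maximum(d, 0.0)
    cum = np.cumsum(d[:, 1:], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cmndf = d[:, 1:] * taus[1:] / np.where(cum > 0, cum, np.inf)
    return np.concatenate([np.ones((n_frames, 1)), cmndf], axis=1)


def _parabolic(y: np.ndarray, i: int) -> float:
    if i <= 0 or i >= y.size - 1:
        return float(i)
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(i)
    return i + 0.5 * (a - c) / denom


def estimate_fo(s: Signal, fmin: float, fmax: float, frame_length: int = 2048,
                hop: int | None = None, threshold: float = 0.1,
                voicing_threshold: float = 0.45, smooth: bool = True) -> FoTrack:
    """YIN fo track with voicing decisions and octave-consistent smoothing.

    Parameters follow the usual convention: ``fmin``/``fmax`` bound the
    search lags, ``threshold`` is the absolute CMNDF dip threshold, frames
    whose minimum CMNDF exceeds ``voicing_threshold`` (or whose RMS is
    negligible) are unvoiced.
    """
    if fmin <= 0 or not fmin < fmax or fmax >= s.fs / 2:
        raise ValueError("need 0 < fmin < fmax < fs/2")
    if s.duration < 2.0 / fmin:
        raise ValueError(f"signal shorter than two periods of fmin={fmin} Hz")
    fs = s.fs
    max_lag_needed = int(np.ceil(fs / fmin))
    frame_length = max(frame_length, 2 * max_lag_needed)
    if hop is None:
        hop = frame_length // 4
    x = s.samples - np.mean(s.samples)
    if x.size < frame_length:
        x = np.pad(x, (0, frame_length - x.size))
    frames = _frame_signal(x, frame_length, hop)
    max_lag = frame_length // 2
    cmndf = _yin_cmndf(frames, max_lag)

    tau_min = max(2, int(np.floor(fs / fmax)))
    tau_max = min(max_lag, int(np.ceil(fs / fmin)))
    n_frames = frames.shape[0]
    fo = np.full(n_frames, np.nan)
    voicing = np.zeros(n_frames)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    floor = 1e-5 * max(rms.max(), 1e-300)
    for i in range(n_frames):
        band = cmndf[i, tau_min:tau_max + 1]
        best = float(band.min())
        voicing[i] = max(0.0, 1.0 - best)
        if rms[i] <= floor or best > voicing_threshold:
            continue
        below = np.flatnonzero(band < threshold)
        if below.size:
            j = below[0]
            while j + 1 < band.size and band[j + 1] < band[j]:
                j += 1
        else:
            j = int(np.argmin(band))
        tau = _parabolic(cmndf[i], j + tau_min)
        if tau > 0:
            fo[i] = fs / tau

    if smooth and np.isfinite(fo).sum() >= 3:
        voiced_idx = np.flatnonzero(np.isfinite(fo))
        filled = np.interp(np.arange(n_frames), voiced_idx, fo[voiced_idx])
        med = medfilt(filled, kernel_size=min(5, 2 * (n_frames // 2) - 1) if n_frames >= 5 else 3)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs(np.log2(fo / med))
        flip = np.isfinite(dev) & (dev > 0.4)
        fo[flip] = med[flip]

    times = s.t0 + (np.arange(n_frames) * hop + frame_length / 2) / fs
    return FoTrack(times=times, fo=fo, voicing=voicing, label=s.label,
                   settings={"fmin": fmin, "fmax": fmax, "frame_length": frame_length,
                             "hop": hop, "threshold": threshold})


# ---------------------------------------------------------------------------
# STFT spectrogram


def stft_spectrogram(s: Signal, spec: SpectrogramSpec | None = None
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-windowed STFT magnitude.

    Returns ``(freqs, times, mag)`` with ``mag[f, t]``.  Magnitudes are
    scaled by ``2 / Σw`` so a unit-amplitude sinusoid gives a peak close to
    1 (one-sided spectrum, window-gain compensated).
    """
    spec = spec or SpectrogramSpec()
    if spec.window_length > len(s):
        raise ValueError("window longer than signal")
    win = hann(spec.window_length, sym=False)
    sft = ShortTimeFFT(win, hop=spec.hop, fs=s.fs, fft_mode="onesided")
    S = sft.stft(s.samples)
    mag = np.abs(S) * 2.0 / win.sum()
    times = s.t0 + sft.t(len(s))
    # keep only frames fully inside the signal (no zero-padding bias)
    half = spec.window_length / 2 / s.fs
    keep = (times >= s.t0 + half - 1e-12) & (times <= s.t0 + s.duration - half + 1e-12)
    if keep.any():
        S_out = mag[:, keep]
        times = times[keep]
    else:
        S_out = mag
    return sft.f, times, S_out


def _peak_interp(mag: np.ndarray, freqs: np.ndarray, i: int) -> tuple[float, float]:
    j = _parabolic(mag, i)
    df = freqs[1] - freqs[0]
    lo = int(np.floor(j))
    frac = j - lo
    f = freqs[0] + j * df
    m = mag[i] if (i <= 0 or i >= mag.size - 1) else (
        mag[lo] * (1 - frac) + mag[min(lo + 1, mag.size - 1)] * frac)
    return float(f), float(max(m, mag[i]))


# ---------------------------------------------------------------------------
# detectors


def _merge_frames_to_events(flags: np.ndarray, times: np.ndarray, kind: str,
                            params_per_frame: list, strengths: np.ndarray,
                            min_frames: int = 1, max_gap_frames: int = 1
                            ) -> list[SpectralEvent]:
    events = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return events
    runs = [[idx[0], idx[0]]]
    for i in idx[1:]:
        if i - runs[-1][1] <= max_gap_frames:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    for i0, i1 in runs:
        span = np.arange(i0, i1 + 1)
        span = span[flags[span]]
        if span.size < min_frames:
            continue
        best = span[int(np.argmax(strengths[span]))]
        events.append(SpectralEvent(kind=kind, t_start=float(times[i0]),
                                    t_end=float(times[i1]),
                                    params=params_per_frame[best],
                                    strength=float(strengths[best])))
    return events


def detect_subharmonics(s: Signal, fo_track: FoTrack | None = None,
                        max_order: int = 4, rel_threshold: float = 0.05,
                        spec: SpectrogramSpec | None = None,
                        band: tuple[float, float] = (20.0, 2000.0),
                        min_frames: int = 2) -> list[SpectralEvent]:
    """Detect spectral components at fo/k (k = 2..max_order).

    Per STFT frame the dominant peak f₁ in ``band`` is located; a
    subharmonic of order k is flagged when a local spectral peak within one
    bin of f₁/k exceeds ``rel_threshold`` of the f₁ magnitude and stands
    above the frame's noise floor.  Consecutive detections merge into
    events carrying the smallest order found.
    """
    spec = spec or SpectrogramSpec(window_length=8192)
    if spec.window_length > len(s):
        spec = SpectrogramSpec(window_length=1 << int(np.floor(np.log2(len(s)))))
    freqs, times, mag = stft_spectrogram(s, spec)
    df = freqs[1] - freqs[0]
    flags = np.zeros(times.size, dtype=bool)
    params: list[dict] = [{} for _ in range(times.size)]
    strengths = np.zeros(times.size)
    lo, hi = np.searchsorted(freqs, band[0]), np.searchsorted(freqs, band[1])
    for ti in range(times.size):
        col = mag[:, ti]
        if fo_track is not None:
            fo_here = np.interp(times[ti], fo_track.times,
                                np.where(fo_track.voiced, fo_track.fo, np.nan),
                                left=np.nan, right=np.nan)
            if not np.isfinite(fo_here):
                continue
        seg = col[lo:hi]
        if seg.size == 0 or seg.max() <= 0:
            continue
        i1 = lo + int(np.argmax(seg))
        f1, m1 = _peak_interp(col, freqs, i1)
        noise_floor = 5.0 * np.median(col[lo:hi])
        for k in range(2, max_order + 1):
            ft = f1 / k
            if ft < band[0] or ft < 2 * df:
                break
            j0 = int(round(ft / df))
            j_lo, j_hi = max(1, j0 - 2), min(col.size - 1, j0 + 3)
            j = j_lo + int(np.argmax(col[j_lo:j_hi]))
            if col[j] < col[j - 1] or col[j] < col[j + 1]:
                continue
            fk, mk = _peak_interp(col, freqs, j)
            if abs(fk - ft) > 1.5 * df:
                continue
            if mk >= rel_threshold * m1 and mk > noise_floor:
                flags[ti] = True
                params[ti] = {"k": k, "fo": f1, "f_sub": fk}
                strengths[ti] = mk / m1
                break
    return _merge_frames_to_events(flags, times, "subharmonic", params,
                                   strengths, min_frames=min_frames)


def detect_frequency_jump(fo_track: FoTrack, min_step: float = 5.0,
                          max_gap: float = 0.05, flank: float = 0.1
                          ) -> list[SpectralEvent]:
    """Change-point detection on an fo track.

    A jump at t requires (i) flanking-window medians differing by at least
    ``min_step`` Hz, (ii) a two-level step model fitting the local track
    better than a linear ramp (rejects glissandi), and (iii) the track
    crossing the middle half of the step in less than ``max_gap`` seconds.
    """
    voiced = fo_track.voiced
    if not voiced.any():
        raise ValueError("fo track is fully unvoiced")
    t = fo_track.times
    fo = fo_track.fo
    n = t.size
    cand_strength = np.zeros(n)
    cand_params: list[dict] = [{} for _ in range(n)]
    dt = float(np.median(np.diff(t)))
    for i in range(1, n - 1):
        pre_m = voiced & (t >= t[i] - flank) & (t < t[i])
        post_m = voiced & (t > t[i]) & (t <= t[i] + flank)
        if pre_m.sum() < 3 or post_m.sum() < 3:
            continue
        pre = float(np.median(fo[pre_m]))
        post = float(np.median(fo[post_m]))
        step = post - pre
        if abs(step) < min_step:
            continue
        # step model vs linear ramp over the local window
        win = pre_m | post_m
        tw, fw = t[win], fo[win]
        step_pred = np.where(tw <= t[i], pre, post)
        sse_step = float(np.sum((fw - step_pred) ** 2))
        A = np.vstack([tw, np.ones_like(tw)]).T
        coef, *_ = np.linalg.lstsq(A, fw, rcond=None)
        sse_lin = float(np.sum((fw - A @ coef) ** 2))
        if sse_step >= sse_lin:
            continue
        band_lo = min(pre, post) + 0.25 * abs(step)
        band_hi = max(pre, post) - 0.25 * abs(step)
        inside = win & (fo > band_lo) & (fo < band_hi)
        if inside.sum() * dt > max_gap:
            continue
        cand_strength[i] = abs(step)
        cand_params[i] = {"fo_pre": pre, "fo_post": post}
    flags = cand_strength > 0
    # keep only the strongest candidate within each flank-sized neighbourhood
    events = _merge_frames_to_events(flags, t, "frequency_jump", cand_params,
                                     cand_strength,
                                     max_gap_frames=max(1, int(round(flank / dt))))
    out = []
    for ev in events:
        i_best = int(np.argmin(np.abs(t - (ev.t_start + ev.t_end) / 2)))
        mid = t[np.flatnonzero(flags & (t >= ev.t_start) & (t <= ev.t_end))]
        tc = float(mid[np.argmax(cand_strength[np.isin(t, mid)])]) if mid.size else t[i_best]
        out.append(SpectralEvent("frequency_jump", tc, tc, ev.params, ev.strength))
    return out


def _is_commensurate(ratio: float, max_order: int, tol: float) -> bool:
    for q in range(1, max_order + 1):
        for p in range(q, max_order + 1):
            target = p / q
            if abs(ratio - target) / target <= tol:
                return True
    return False


def detect_biphonation(s: Signal, spec: SpectrogramSpec | None = None,
                       max_order: int = 6, ratio_tol: float = 0.02,
                       min_rel: float = 0.1, min_frames: int = 3,
                       band: tuple[float, float] = (20.0, 2000.0)
                       ) -> list[SpectralEvent]:
    """Flag intervals with two incommensurate narrowband components.

    Per frame the two strongest prominent peaks are taken; the frame is
    flagged when the second is at least ``min_rel`` of the first and their
    frequency ratio is not within ``ratio_tol`` of any p/q with
    p, q ≤ ``max_order``.  Runs of at least ``min_frames`` flagged frames
    with stable component frequencies become events.  Broadband (chaotic)
    signals fail the narrowband-peak requirement and are not flagged.
    """
    spec = spec or SpectrogramSpec(window_length=8192)
    if spec.window_length > len(s):
        spec = SpectrogramSpec(window_length=1 << int(np.floor(np.log2(len(s)))))
    freqs, times, mag = stft_spectrogram(s, spec)
    lo, hi = np.searchsorted(freqs, band[0]), np.searchsorted(freqs, band[1])
    flags = np.zeros(times.size, dtype=bool)
    params: list[dict] = [{} for _ in range(times.size)]
    strengths = np.zeros(times.size)
    f_pairs = np.full((times.size, 2), np.nan)
    for ti in range(times.size):
        col = mag[lo:hi, ti]
        if col.max() <= 0:
            continue
        floor = np.median(col)
        peaks, props = find_peaks(col, height=5.0 * floor, prominence=3.0 * floor)
        if peaks.size < 2:
            continue
        order = np.argsort(props["peak_heights"])[::-1][:2]
        p2 = peaks[order]
        h2 = props["peak_heights"][order]
        if h2[1] < min_rel * h2[0]:
            continue
        fvals = sorted(_peak_interp(mag[:, ti], freqs, lo + p)[0] for p in p2)
        ratio = fvals[1] / fvals[0]
        if _is_commensurate(ratio, max_order, ratio_tol):
            continue
        flags[ti] = True
        f_pairs[ti] = fvals
        params[ti] = {"f_low": fvals[0], "f_high": fvals[1], "ratio": ratio}
        strengths[ti] = h2[1] / h2[0]
    events = _merge_frames_to_events(flags, times, "biphonation", params,
                                     strengths, min_frames=min_frames)
    # require the two components to be stable over the event
    stable = []
    for ev in events:
        m = flags & (times >= ev.t_start) & (times <= ev.t_end)
        fp = f_pairs[m]
        if fp.shape[0] >= min_frames and np.all(
                np.nanstd(fp, axis=0) / np.nanmean(fp, axis=0) < 0.02):
            stable.append(ev)
    return stable


# ---------------------------------------------------------------------------
# periodicity index


def periodicity_index(s: Signal, window_s: float, min_period_s: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window peak of the normalised autocorrelation at lags ≥ one period.

    Values near 1 indicate strong periodicity; broadband/chaotic windows
    stay low.  ``window_s`` must cover at least two expected periods.
    Returns (window centre times, index values).
    """
    L = int(round(window_s * s.fs))
    if L > len(s):
        raise ValueError("window longer than signal")
    min_lag = max(1, int(round(min_period_s * s.fs)))
    if L < 2 * min_lag:
        raise ValueError("window must cover at least two expected periods")
    n_win = len(s) // L
    centers = s.t0 + (np.arange(n_win) + 0.5) * L / s.fs
    out = np.zeros(n_win)
    for k in range(n_win):
        x = s.samples[k * L:(k + 1) * L].astype(float)
        x = x - x.mean()
        denom = float(np.dot(x, x))
        if denom <= 0:
            out[k] = 0.0
            continue
        nfft = 1 << int(np.ceil(np.log2(2 * L)))
        ac = np.fft.irfft(np.abs(np.fft.rfft(x, nfft)) ** 2, nfft)[:L]
        ac = ac / denom
        hi = max(min_lag + 1, L // 2)
        out[k] = float(ac[min_lag:hi].max()) if min_lag < hi else 0.0
    return centers, out
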