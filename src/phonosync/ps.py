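"""Hilbert-transform phase synchrony between two channels.

The synchrony statistic is the cosine of the absolute instantaneous phase
difference of the two analytic signals,

    PS(t) = cos( |∠(a + jH{a}) − ∠(b + jH{b})| ),

bounded in [−1, 1]: +1 for in-phase signals, −1 for a 180° shift, and 0
either for equal-frequency signals in quadrature (then with zero spread)
or when the prominent frequencies are in an integer ratio (then the phase
difference sweeps the circle uniformly within each window and the windowed
median sits near 0).

Windowing uses a variable window length ``Nwin = floor(Fs / fo_min)`` with

* group 1 (quasi-periodic, entrained): fo_min = 0.2 · min(fo_iEGG, fo_audio),
* group 2 (irregular): fo_min = 20 Hz,

and non-overlapping windows by default.  Each window is summarised by its
median, 25 % and 75 % quantiles (IQR = q75 − q25).  Windows in which either
channel is effectively silent are reported as missing rather than 0, since
a phase is undefined there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .io import Signal

GROUP2_FO_MIN = 20.0  # Hz


@dataclass
class PSOptions:
    """Windowing, band-pass and edge options for windowed phase synchrony."""

    fs: float
    fo_min: float
    bandpass: tuple[float, float] | None = None
    hop: int | None = None            # default: non-overlapping (hop = Nwin)
    edge_fraction: float = 0.02       # trimmed from both ends (Hilbert edges)
    filter_ps_series: bool = False    # low-pass the PS series instead of inputs
    min_valid_fraction: float = 0.5
    silence_rtol: float = 1e-8

    def __post_init__(self) -> None:
        if self.fo_min <= 0:
            raise ValueError("fo_min must be positive")
        if self.nwin < 2:
            raise ValueError("window shorter than 2 samples")
        if self.bandpass is not None:
            lo, hi = self.bandpass
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError("bandpass must satisfy 0 < low < high < fs/2")

    @property
    def nwin(self) -> int:
        """Window length in samples, floor(fs / fo_min)."""
        return int(math.floor(self.fs / self.fo_min))

    @classmethod
    def group1(cls, fs: float, fo_iegg: float, fo_audio: float, **kw) -> "PSOptions":
        """Quasi-periodic group: fo_min = 0.2·min(fo_iEGG, fo_audio)."""
        return cls(fs=fs, fo_min=0.2 * min(fo_iegg, fo_audio), **kw)

    @classmethod
    def group2(cls, fs: float, **kw) -> "PSOptions":
        """Irregular group: fixed fo_min = 20 Hz."""
        return cls(fs=fs, fo_min=GROUP2_FO_MIN, **kw)


def default_band(fo_min: float, fo_est: float, fs: float) -> tuple[float, float]:
    """Default analysis band [0.5·fo_min, 10·fo_est], clipped below Nyquist."""
    return (0.5 * fo_min, min(10.0 * fo_est, 0.45 * fs))


@dataclass
class PSSeries:
    """Per-window phase-synchrony summaries."""

    t_center: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_valid: np.ndarray
    nwin: int

    @property
    def iqr(self) -> np.ndarray:
        return self.q75 - self.q25

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.median)

    def interior(self, drop: int = 1) -> "PSSeries":
        """Drop the first/last ``drop`` windows (Hilbert edge caution)."""
        sl = slice(drop, len(self.t_center) - drop if drop else None)
        return PSSeries(self.t_center[sl], self.median[sl], self.q25[sl],
                        self.q75[sl], self.n_valid[sl], self.nwin)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_center": self.t_center, "median": self.median,
                             "q25": self.q25, "q75": self.q75,
                             "iqr": self.iqr, "n_valid": self.n_valid})


def instantaneous_phase(s: Signal) -> np.ndarray:
    """Phase of the analytic signal (radians, wrapped to (−π, π]).

    The mean is removed before the Hilbert transform.  Only phase
    *differences* mod 2π enter the synchrony statistic, so no unwrapping is
    performed.
    """
    x = s.samples - np.mean(s.samples)
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    return np.angle(hilbert(x))


def pointwise_ps(a: Signal, b: Signal) -> np.ndarray:
    """cos(|Δphase|) per sample; symmetric in (a, b) and bounded in [−1, 1]."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if a.fs != b.fs:
        raise ValueError(f"sampling-rate mismatch: {a.fs} vs {b.fs}")
    return np.cos(np.abs(instantaneous_phase(a) - instantaneous_phase(b)))


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def windowed_ps(a: Signal, b: Signal, opts: PSOptions) -> PSSeries:
    """Band-pass (optional), compute pointwise PS, summarise per window.

    Windows with fewer than ``min_valid_fraction·Nwin`` usable samples —
    edge-trimmed samples or windows where either channel is effectively
    silent — are reported as missing (NaN), not zero.
    """
    if len(a) != len(b):
        raise ValueError("length mismatch")
    nwin = opts.nwin
    n = len(a)
    if nwin > n:
        raise ValueError(f"window ({nwin}) longer than signal ({n})")
    hop = opts.hop or nwin

    xa, xb = a.samples, b.samples
    if opts.bandpass is not None and not opts.filter_ps_series:
        xa = _bandpass(xa - xa.mean(), opts.bandpass, opts.fs)
        xb = _bandpass(xb - xb.mean(), opts.bandpass, opts.fs)
    sa = Signal(xa, fs=a.fs, t0=a.t0, label=a.label)
    sb = Signal(xb, fs=b.fs, t0=b.t0, label=b.label)
    ps = pointwise_ps(sa, sb)
    if opts.bandpass is not None and opts.filter_ps_series:
        sos = butter(4, opts.bandpass[1], btype="lowpass", fs=opts.fs, output="sos")
        ps = np.clip(sosfiltfilt(sos, ps), -1.0, 1.0)

    edge = int(round(opts.edge_fraction * n))
    valid = np.ones(n, dtype=bool)
    if edge:
        valid[:edge] = False
        valid[n - edge:] = False

    tol_a = opts.silence_rtol * max(float(np.max(np.abs(xa))), 1e-300)
    tol_b = opts.silence_rtol * max(float(np.max(np.abs(xb))), 1e-300)

    n_windows = 1 + (n - nwin) // hop
    t_center = a.t0 + (np.arange(n_windows) * hop + nwin / 2) / a.fs
    med = np.full(n_windows, np.nan)
    q25 = np.full(n_windows, np.nan)
    q75 = np.full(n_windows, np.nan)
    n_valid = np.zeros(n_windows, dtype=int)
    for k in range(n_windows):
        sl = slice(k * hop, k * hop + nwin)
        wa, wb = xa[sl], xb[sl]
        if np.sqrt(np.mean(wa**2)) <= tol_a or np.sqrt(np.mean(wb**2)) <= tol_b:
            continue  # silent channel: PS undefined, window missing
        vals = ps[sl][valid[sl]]
        if vals.size < opts.min_valid_fraction * nwin:
            continue
        q = np.percentile(vals, [25, 50, 75])
        q25[k], med[k], q75[k] = q[0], q[1], q[2]
        n_valid[k] = vals.size
    return PSSeries(t_center=t_center, median=med, q25=q25, q75=q75,
                    n_valid=n_valid, nwin=nwin)
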