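"""Signal and frame-stack containers plus file I/O.

All channels of a phonation recording (acoustic pressure, electroglottogram,
area waveforms derived from high-speed imaging) are held as :class:`Signal`
objects sharing one sampling rate inside a :class:`Recording`.  Two signal
conventions used throughout the package live here:

* ``invert_egg`` — the electroglottogram is sign-inverted (iEGG = −EGG) so
  that, like the glottal/supraglottic area waveforms, large values mean an
  open (minimal-contact) configuration.
* ``normalize_max_abs`` — every non-audio channel is scaled by its maximum
  absolute value before spectral analysis.

Supported formats: mono WAV per channel (PCM 16/24/32-bit and float32),
comma-separated tables with a header row (optional leading ``time_s``
column), PNG image sequences and multi-page TIFF for frame stacks.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy.io import wavfile
from scipy.signal import resample_poly

CHANNEL_LABELS = ("audio", "EGG", "iEGG", "GAW", "SAW", "other")


@dataclass
class Signal:
    """A uniformly sampled real-valued channel.

    Parameters
    ----------
    samples : ndarray
        1-D float array, dimensionless (area waveforms are in px² until
        normalised).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.  All channels of a simultaneous
        acquisition default to ``t0 = 0``.
    label : str
        One of ``audio, EGG, iEGG, GAW, SAW, other``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "other"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if self.label not in CHANNEL_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CHANNEL_LABELS}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def crop(self, t_start: float, t_end: float) -> "Signal":
        i0 = max(0, int(round((t_start - self.t0) * self.fs)))
        i1 = min(len(self), int(round((t_end - self.t0) * self.fs)))
        if i1 <= i0:
            raise ValueError(f"empty crop [{t_start}, {t_end}] s")
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)


@dataclass
class FrameStack:
    """A sequence of constant-size grayscale frames in [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class Recording:
    """Labelled set of aligned channels plus an optional frame stack."""

    channels: dict[str, Signal] = field(default_factory=dict)
    frames: FrameStack | None = None

    def __post_init__(self) -> None:
        lengths = {lab: len(s) for lab, s in self.channels.items()}
        rates = {s.fs for s in self.channels.values()}
        t0s = {s.t0 for s in self.channels.values()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel lengths differ: {lengths}")
        if len(rates) > 1:
            raise ValueError(f"channel sampling rates differ: {rates}")
        if len(t0s) > 1:
            raise ValueError(f"channel time origins differ: {t0s}")

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def __getitem__(self, label: str) -> Signal:
        return self.channels[label]

    def __contains__(self, label: str) -> bool:
        return label in self.channels


# ---------------------------------------------------------------------------
# signal conventions


def invert_egg(egg: Signal) -> Signal:
    """Sign-invert an electroglottogram: iEGG = −EGG.

    After inversion a positive value corresponds to an open glottis, the same
    orientation as the glottal/supraglottic area waveforms, so maxima of iEGG
    line up with maxima of GAW/SAW.
    """
    if egg.label != "EGG":
        raise ValueError(f"invert_egg expects label 'EGG', got {egg.label!r}")
    return replace(egg, samples=-egg.samples, label="iEGG")


def normalize_max_abs(s: Signal) -> Signal:
    """Scale a signal by its maximum absolute value (peak at ±1)."""
    peak = float(np.max(np.abs(s.samples))) if len(s) else 0.0
    if peak == 0.0:
        raise ValueError("cannot normalise an all-zero signal")
    return replace(s, samples=s.samples / peak)


def resample_signal(s: Signal, target_fs: float, max_denominator: int = 1000) -> Signal:
    """Polyphase rational resampling with anti-alias filtering."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == s.fs:
        return replace(s)
    frac = Fraction(target_fs / s.fs).limit_denominator(max_denominator)
    out = resample_poly(s.samples, frac.numerator, frac.denominator)
    n_target = int(round(len(s) * target_fs / s.fs))
    out = out[:n_target]
    if out.size < n_target:
        out = np.pad(out, (0, n_target - out.size))
    return replace(s, samples=out, fs=target_fs)


# ---------------------------------------------------------------------------
# WAV


def read_wav(path: str | os.PathLike, label: str = "other") -> Signal:
    fs, data = wavfile.read(os.fspath(path))
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono WAV, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:  # float32/float64
        samples = data.astype(float)
    return Signal(samples, fs=float(fs), label=label)


def write_wav(path: str | os.PathLike, s: Signal, dtype: str = "float32") -> None:
    """Write a mono WAV; ``dtype`` is ``'float32'`` or ``'int16'``."""
    if dtype == "int16":
        data = np.clip(np.round(s.samples * 32768.0), -32768, 32767).astype(np.int16)
    elif dtype == "float32":
        data = s.samples.astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(os.fspath(path), int(round(s.fs)), data)


# ---------------------------------------------------------------------------
# delimited tables (CSV dialect: header row, optional first column time_s)


def read_table(path: str | os.PathLike, fs: float | None = None) -> dict[str, Signal]:
    """Read a multi-channel CSV table into labelled signals.

    If the table has a ``time_s`` column the sampling rate is inferred from it
    (timestamps must be uniform and strictly increasing); otherwise ``fs``
    must be given.
    """
    df = pd.read_csv(path)
    t0 = 0.0
    if "time_s" in df.columns:
        t = df.pop("time_s").to_numpy(float)
        dt = np.diff(t)
        if t.size > 1 and np.any(dt <= 0):
            raise ValueError(f"{path}: non-monotone timestamps")
        if t.size > 1 and not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform timestamps")
        fs = 1.0 / dt[0] if t.size > 1 else (fs or 1.0)
        t0 = float(t[0])
    elif fs is None:
        raise ValueError(f"{path}: no time_s column and no fs given")
    out = {}
    for col in df.columns:
        label = col if col in CHANNEL_LABELS else "other"
        out[col] = Signal(df[col].to_numpy(float), fs=float(fs), t0=t0, label=label)
    return out


def write_table(path: str | os.PathLike, channels: Mapping[str, Signal],
                include_time: bool = True) -> None:
    sigs = dict(channels)
    first = next(iter(sigs.values()))
    data = {}
    if include_time:
        data["time_s"] = first.times
    for name, s in sigs.items():
        if len(s) != len(first):
            raise ValueError("channels of unequal length; align before writing")
        data[name] = s.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# frame stacks


def read_frames(path_or_paths, fps: float, bit_depth: int = 8) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or a PNG/TIFF sequence."""
    if isinstance(path_or_paths, (str, os.PathLike)):
        p = Path(path_or_paths)
        if p.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(p)
        else:
            arr = iio.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        arr = np.stack([iio.imread(p) for p in path_or_paths])
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 4:  # colour → luminance
        arr = arr.mean(axis=-1)
    scale = float(2**bit_depth - 1)
    return FrameStack(arr / scale if arr.max() > 1.0 else arr, fps=fps, bit_depth=bit_depth)


def write_frames(path: str | os.PathLike, stack: FrameStack) -> None:
    """Write a frame stack as a multi-page TIFF (8- or 16-bit)."""
    if stack.bit_depth <= 8:
        arr = np.clip(np.round(stack.frames * 255), 0, 255).astype(np.uint8)
    else:
        arr = np.clip(np.round(stack.frames * 65535), 0, 65535).astype(np.uint16)
    tifffile.imwrite(os.fspath(path), arr)


# ---------------------------------------------------------------------------
# recording-level round trip


def read_recording(paths: Mapping[str, str | os.PathLike],
                   target_fs: float | None = None,
                   frames_path=None, fps: float | None = None,
                   table_fs: float | None = None) -> Recording:
    """Assemble a recording from per-channel files.

    ``paths`` maps a channel label to a WAV or CSV file (CSV files may hold
    several columns; the column matching the label is taken).  Channels are
    resampled to ``target_fs`` when given; otherwise all inputs must already
    share one rate.
    """
    channels: dict[str, Signal] = {}
    for label, path in paths.items():
        suffix = Path(path).suffix.lower()
        if suffix == ".wav":
            s = read_wav(path, label=label if label in CHANNEL_LABELS else "other")
        elif suffix in (".csv", ".txt", ".tsv"):
            table = read_table(path, fs=table_fs)
            if label in table:
                s = table[label]
            elif len(table) == 1:
                s = next(iter(table.values()))
            else:
                raise ValueError(f"{path}: column {label!r} not found")
            s = replace(s, label=label if label in CHANNEL_LABELS else "other")
        else:
            raise ValueError(f"unknown format {suffix!r} for {path}")
        if target_fs is not None:
            s = resample_signal(s, target_fs)
        channels[label] = s
    if len({len(s) for s in channels.values()}) > 1:
        if target_fs is None:
            raise ValueError("channel lengths differ; pass target_fs to align")
        n = min(len(s) for s in channels.values())
        channels = {lab: replace(s, samples=s.samples[:n]) for lab, s in channels.items()}
    frames = None
    if frames_path is not None:
        if fps is None:
            raise ValueError("fps required when reading frames")
        frames = read_frames(frames_path, fps=fps)
    return Recording(channels=channels, frames=frames)


def write_recording(rec: Recording, out_dir: str | os.PathLike,
                    table_name: str = "channels.csv") -> list[Path]:
    """Write all channels to one CSV table (plus frames.tif when present)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    table_path = out / table_name
    write_table(table_path, rec.channels)
    paths.append(table_path)
    if rec.frames is not None:
        fp = out / "frames.tif"
        write_frames(fp, rec.frames)
        paths.append(fp)
    return paths
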