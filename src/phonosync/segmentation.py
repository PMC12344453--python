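"""Area-waveform extraction from grayscale frame stacks.

The glottal area waveform (GAW) and the supraglottic area waveform (SAW)
are both obtained by the same threshold segmentation; they differ only in
the contrast/threshold profile.  A high threshold picks out the brightest
(glottal) region; a lower threshold admits the dimmer supraglottic region
as well, so the resulting SAW aggregates all vibrating areas above
threshold without distinguishing anatomical structures — it carries no
contact-area semantics.

Per frame: contrast is applied (``clip(gain·I + offset, 0, 1)``), pixels at
or above ``grey_threshold`` inside the ROI are binarised, 4-connected
regions smaller than ``min_region_px`` are discarded as speckle, and the
area is the total retained pixel count (integer px², uncalibrated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.transform import rotate as sk_rotate

from .io import FrameStack


@dataclass
class SegmentationProfile:
    """Contrast/threshold recipe for one target region."""

    grey_threshold: float
    target: str = "glottal"            # 'glottal' | 'supraglottic'
    contrast_gain: float = 1.0
    contrast_offset: float = 0.0
    roi: tuple[int, int, int, int] | None = None  # (row0, row1, col0, col1)
    min_region_px: int = 5
    bright_is_open: bool = True        # False inverts intensities first

    def __post_init__(self) -> None:
        if not 0 <= self.grey_threshold <= 1:
            raise ValueError("grey_threshold must be in [0, 1]")
        if self.target not in ("glottal", "supraglottic"):
            raise ValueError("target must be 'glottal' or 'supraglottic'")
        if not np.isfinite(self.contrast_gain):
            raise ValueError("contrast_gain must be finite")


@dataclass
class AreaWaveform:
    """Per-frame segmented region area in px² (uncalibrated)."""

    areas: np.ndarray
    fps: float
    target: str
    profile: SegmentationProfile | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return self.areas.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fps

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_index": np.arange(len(self)),
                             "time_s": self.times, "area_px2": self.areas})

    def to_signal(self, label: str | None = None):
        from .io import Signal
        return Signal(self.areas, fs=self.fps,
                      label=label or ("GAW" if self.target == "glottal" else "SAW"))


def preprocess_frames(stack: FrameStack, rotation_deg: float = 0.0,
                      crop: tuple[int, int, int, int] | None = None,
                      gain: float = 1.0, offset: float = 0.0) -> FrameStack:
    """Rotate, crop and contrast-adjust a frame stack.

    Rotation uses the standard image convention (counter-clockwise about the
    frame centre); multiples of 90° are exact, other angles are
    interpolated.  Crop is ``(row0, row1, col0, col1)`` applied after
    rotation.  Intensities are mapped ``clip(gain·I + offset, 0, 1)``.
    """
    if not np.isfinite(gain):
        raise ValueError("gain must be finite")
    frames = stack.frames
    if rotation_deg % 360 != 0:
        if rotation_deg % 90 == 0:
            k = int(rotation_deg // 90) % 4
            frames = np.rot90(frames, k=k, axes=(1, 2))
        else:
            frames = np.stack([sk_rotate(f, rotation_deg, preserve_range=True)
                               for f in frames])
    if crop is not None:
        r0, r1, c0, c1 = crop
        h, w = frames.shape[1:]
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"empty or out-of-bounds crop {crop} for frame {h}x{w}")
        frames = frames[:, r0:r1, c0:c1]
    frames = np.clip(gain * frames + offset, 0.0, 1.0)
    return FrameStack(frames, fps=stack.fps, bit_depth=stack.bit_depth)


def _segment_frame(img: np.ndarray, profile: SegmentationProfile) -> int:
    if not profile.bright_is_open:
        img = 1.0 - img
    img = np.clip(profile.contrast_gain * img + profile.contrast_offset, 0.0, 1.0)
    binary = img >= profile.grey_threshold
    if not binary.any():
        return 0
    if profile.min_region_px <= 1:
        return int(binary.sum())
    labels = cc_label(binary, connectivity=1)
    counts = np.bincount(labels.ravel())
    keep = counts >= profile.min_region_px
    keep[0] = False
    return int(counts[keep].sum())


def segment_area(stack: FrameStack, profile: SegmentationProfile) -> AreaWaveform:
    """Segment every frame and return the area waveform.

    Multiple retained regions are summed: the waveform aggregates all
    vibrating areas above threshold.  If the threshold saturates (every
    pixel of every frame is foreground) the segmentation is uninformative; a
    warning is raised and zeros are returned.
    """
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    frames = stack.frames
    h, w = stack.frame_shape
    if profile.roi is not None:
        r0, r1, c0, c1 = profile.roi
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"roi {profile.roi} outside frame {h}x{w}")
        frames = frames[:, r0:r1, c0:c1]
    areas = np.array([_segment_frame(f, profile) for f in frames], dtype=float)
    npix = frames.shape[1] * frames.shape[2]
    if np.all(areas == npix):
        warnings.warn("grey_threshold saturates every frame; returning zeros",
                      stacklevel=2)
        areas = np.zeros_like(areas)
    return AreaWaveform(areas=areas, fps=stack.fps, target=profile.target,
                        profile=profile)
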