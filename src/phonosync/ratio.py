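"""Glottal:supraglottic oscillation-ratio estimation and regime labels.

Entrained phonation modes lock the two oscillators at small integer ratios
n:1 (n glottal cycles per supraglottic cycle) — constant for some voice
qualities, stepping through integers during a glissando for others.  The
estimator snaps the ratio of mean fo values to the nearest small integer
and reports a confidence that decays with the residual and with the
variability of the tracks, so incommensurate (biphonation) pairs come out
with low confidence rather than a spurious lock.

Regime taxonomy: group 1 = quasi-periodic, entrained (high periodicity and
a confident integer ratio); group 2 = irregular, split by whether the
glottis was visible in the imaging (2a) or hidden behind supraglottic
constriction (2b).  Visibility is an endoscopic judgement and therefore an
explicit input flag, never inferred from pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral import FoTrack

DEFAULT_N_MAX = 8
DEFAULT_RATIO_TOL = 0.08       # relative tolerance for accepting n
THETA_PERIODICITY = 0.7        # group-1 periodicity threshold
THETA_RATIO_CONF = 0.6         # group-1 ratio-confidence threshold


@dataclass
class RatioEstimate:
    """Integer oscillation ratio over a time interval."""

    n: int
    confidence: float
    t_start: float
    t_end: float
    ratio_raw: float = math.nan          # mean(fo_g)/mean(fo_s) before snapping
    orientation: str = "glottal_over_supraglottic"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.confidence = float(min(max(self.confidence, 0.0), 1.0))


@dataclass
class RegimeFeatures:
    """Evidence entering the group-1/2a/2b decision."""

    periodicity: float            # mean periodicity index on the interval
    ratio_confidence: float
    glottis_visible: bool


@dataclass
class RegimeLabel:
    group: str                    # 'group1' | 'group2a' | 'group2b'
    evidence: RegimeFeatures


def _voiced_stats(track: FoTrack, t_start: float | None, t_end: float | None
                  ) -> tuple[float, float, float]:
    m = track.voiced
    total = np.ones_like(m)
    if t_start is not None:
        sel = track.times >= t_start
        m = m & sel
        total = total & sel
    if t_end is not None:
        sel = track.times <= t_end
        m = m & sel
        total = total & sel
    cov = m.sum() / max(int(np.sum(total)), 1)
    if not m.any():
        return math.nan, math.nan, 0.0
    vals = track.fo[m]
    return float(vals.mean()), float(vals.std()), float(cov)


def estimate_ratio(fo_glottal: FoTrack, fo_supraglottic: FoTrack,
                   interval: tuple[float, float] | None = None,
                   n_max: int = DEFAULT_N_MAX,
                   tol: float = DEFAULT_RATIO_TOL) -> RatioEstimate:
    """Snap mean(fo_glottal)/mean(fo_supraglottic) to the nearest integer n.

    Confidence combines the snapping residual (zero confidence at or beyond
    ``tol`` relative residual) and the coefficient of variation of both
    tracks.  Requires both tracks voiced over at least half the interval.
    """
    t0, t1 = interval if interval is not None else (None, None)
    mg, sg, cov_g = _voiced_stats(fo_glottal, t0, t1)
    ms, ss, cov_s = _voiced_stats(fo_supraglottic, t0, t1)
    if cov_g < 0.5 or cov_s < 0.5 or not (np.isfinite(mg) and np.isfinite(ms)):
        raise ValueError("tracks must be voiced over at least 50% of the interval")
    r = mg / ms
    orientation = "glottal_over_supraglottic"
    if r < 1.0:
        r = 1.0 / r
        orientation = "supraglottic_over_glottal"
    if r > n_max + 0.5:
        raise ValueError(f"ratio {r:.2f} outside [1/{n_max}, {n_max}]")
    n = int(min(max(round(r), 1), n_max))
    residual = abs(r - n) / n
    conf_resid = max(0.0, 1.0 - residual / tol)
    cv = sg / mg + ss / ms
    confidence = conf_resid / (1.0 + 5.0 * cv)
    ts = t0 if t0 is not None else float(min(fo_glottal.times[0], fo_supraglottic.times[0]))
    te = t1 if t1 is not None else float(max(fo_glottal.times[-1], fo_supraglottic.times[-1]))
    return RatioEstimate(n=n, confidence=confidence, t_start=ts, t_end=te,
                         ratio_raw=mg / ms, orientation=orientation)


def track_ratio(fo_glottal: FoTrack, fo_supraglottic: FoTrack, window_s: float,
                n_max: int = DEFAULT_N_MAX, tol: float = DEFAULT_RATIO_TOL
                ) -> tuple[list[RatioEstimate], list[float]]:
    """Per-window ratio estimates plus change-point times where n changes.

    Windows failing the voicing precondition are skipped (no estimate);
    change-points are reported between consecutive *valid* windows whose
    integer ratio differs.
    """
    t0 = float(min(fo_glottal.times[0], fo_supraglottic.times[0]))
    t1 = float(max(fo_glottal.times[-1], fo_supraglottic.times[-1]))
    estimates: list[RatioEstimate] = []
    t = t0
    while t + window_s <= t1 + 1e-9:
        try:
            est = estimate_ratio(fo_glottal, fo_supraglottic, (t, t + window_s),
                                 n_max=n_max, tol=tol)
            estimates.append(est)
        except ValueError:
            pass
        t += window_s
    changepoints = []
    for prev, cur in zip(estimates, estimates[1:]):
        if cur.n != prev.n:
            changepoints.append(0.5 * (prev.t_end + cur.t_start))
    return estimates, changepoints


def classify_group(features: RegimeFeatures,
                   theta_p: float = THETA_PERIODICITY,
                   theta_r: float = THETA_RATIO_CONF) -> RegimeLabel:
    """Assign group1 / group2a / group2b from computed evidence.

    group 1 requires both a high mean periodicity index and a confident
    integer oscillation ratio; otherwise group 2, split by the
    ``glottis_visible`` flag.  Deterministic: identical features always map
    to the same label.
    """
    if not (np.isfinite(features.periodicity) and np.isfinite(features.ratio_confidence)):
        raise ValueError("missing features")
    if features.periodicity >= theta_p and features.ratio_confidence >= theta_r:
        group = "group1"
    else:
        group = "group2a" if features.glottis_visible else "group2b"
    return RegimeLabel(group=group, evidence=features)


def ratio_table(estimates: list[RatioEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "t_start": e.t_start, "t_end": e.t_end, "n": e.n,
        "ratio_raw": e.ratio_raw, "confidence": e.confidence,
        "orientation": e.orientation,
    } for e in estimates])
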