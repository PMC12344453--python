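# Methods

This note documents the models, parameter choices and numerical decisions
behind `phonosync`, and what the synthetic test material does and does not
establish about real recordings.

## Signal model and conventions

All channels are treated as simultaneously triggered (common t0 = 0) and
share one sampling rate, nominally Fs = 20 kHz with frame rate equal to the
signal rate (frame = sample at 20 000 fps, 386×320 px). Resampling, when a
channel arrives at a different rate, is polyphase rational resampling with
its built-in anti-alias filter. An explicit per-channel offset option
exists but defaults to zero; no inter-device synchronisation correction is
applied.

The electroglottogram is sign-inverted, iEGG = −1·EGG, so that maxima of
iEGG, GAW and SAW all correspond to an open (minimal-contact)
configuration. Non-audio channels are normalised by their maximum absolute
value before spectral analysis; `normalize_max_abs` is idempotent and
positive-scale invariant, and refuses all-zero input rather than emitting
NaN.

## Synthetic coupled-oscillator scenes

The generator stands in for in-vivo multi-channel recordings, so its
defaults are the study conditions rather than free dials.

* **Oscillators.** Glottal and supraglottic sources are pulse trains
  obtained by accumulating phase over a piecewise-linear fo trajectory
  (constant / glissando / step). The default pulse is a raised cosine
  occupying an open quotient of 0.6 of each cycle — differentiable,
  band-limited, and EGG-like; impulse trains and sinusoids are available.
  Glottal fo spans the phonation range of interest (~44–280 Hz for the
  constant qualities, up to ~500 Hz at the top of ratio-stepping glides);
  supraglottic rates cluster near 55–80 Hz as observed for ventricular-fold
  co-oscillation.
* **Locked regime.** The supraglottic phase is derived from the glottal
  phase, φ_s = φ_g/n + offset, so n:1 entrainment is exact even through
  glissandi and jumps. Ground-truth fo and ratio trajectories are emitted
  per sample.
* **Drifting.** The supraglottic oscillator integrates fo_g/n detuned by a
  slow ±2 % sinusoid (0.7 Hz): near-locked behaviour without hard locking.
* **Biphonation.** fo_s = fo_g·(φ−1)/n with φ the golden ratio — the most
  irrational frequency relation, so no small-integer ratio approximates it
  within the detectors' tolerance.
* **Chaotic.** Cycle lengths are jittered ±20 % by a logistic map at r = 4
  (arcsine-distributed iterates, seeded away from the unstable fixed
  points); successive iterates also set each cycle's amplitude in (0, 1)
  and a pulse-width factor in (0.5, 1). Period jitter alone leaves a
  smooth 72 %-duty pulse train substantially self-similar at a one-period
  lag; chaotic phonation varies level and cycle shape as well as timing,
  and with all three driven by the map the supraglottic channel's
  normalised autocorrelation stays below 0.5 at all lags ≥ one nominal
  period on 2 s scenes.
* **Period doubling.** Supraglottic contact damps every other glottal pulse:
  the iEGG-like channel is the glottal waveform multiplied by
  (1 − depth) on alternating cycles. Note the *fundamental* of the damped
  signal is then fo/2 — which is why Table-style fo readings of the iEGG
  equal the supraglottic rate during 2:1 entrainment, and why the regime
  classifier takes the glottal oscillation rate from the (unmodulated) GAW
  channel when available.
* **Audio mix.** audio = 0.7·(modulated glottal) + 0.3·(normalised
  d(SAW)/dt) + noise. No physiological mixing model is claimed; the weights
  are configurable scene parameters, not statements about physiology.
* **Noise.** Additive white Gaussian at a stated SNR, applied per channel,
  deterministic per seed. Identical scene spec + seed ⇒ bit-identical
  channels.

### Frame rendering

Frames contain a central glottal ellipse (aspect 3:1) and a surrounding
supraglottic annulus over a uniform background, at three distinct grey
levels (0.10 / 0.55 / 0.90 by default; any distinct ordering is allowed
since endoscopic polarity varies). Pixels of each region are switched on in
order of elliptical radius, so the rendered pixel area equals the requested
area exactly up to integer rounding — the stack is its own segmentation
oracle. A small irrational centre offset avoids radius ties on the integer
grid.

## Area segmentation

Per frame: optional intensity inversion (`bright_is_open=False`), contrast
map clip(gain·I + offset, 0, 1), binarisation at the grey threshold inside
the ROI, 4-connected labelling, removal of regions smaller than
`min_region_px` (default 5 px, a cheap deterministic despeckle), and
summation of all retained pixels. Areas are integer pixel counts; no
sub-pixel estimation and no calibration to mm². Lowering the threshold at
fixed contrast can only grow the above-threshold pixel set, so segmented
area is monotone in the threshold even with despeckling. A threshold that
saturates every pixel of every frame yields a warning and zeros. Numeric
contrast/threshold values are per-recording free parameters; the glottal
target uses a high threshold (bright inner region only) and the
supraglottic target a lower one, which deliberately aggregates every
vibrating area above threshold.

## fo estimation

`estimate_fo` is a YIN-family estimator: per frame (default 2048 samples,
grown automatically to cover two periods of fmin; hop = frame/4) the
difference function is computed by FFT correlation with integration length
frame − max_lag, normalised to the CMNDF, and the first lag dipping below
the absolute threshold 0.1 (descending to its local minimum) is refined by
parabolic interpolation. Frames whose best CMNDF exceeds 0.45, or whose
RMS is below 10⁻⁵ of the loudest frame, are unvoiced;
voicing confidence is 1 − min(CMNDF). A 5-point median filter plus an
octave guard (voiced frames more than 0.4 octaves from the running median
are snapped to it) suppresses fo/2–2fo flips; on clean tones the estimator
is well inside 1 % of truth. Segment summaries are mean ± SD over voiced
frames in a stated interval, the convention used for sustained-phonation
tables.

## Spectrogram and event detectors

STFT uses a Hann window (2048 samples for general inspection; the detectors
default to 8192 at 20 kHz, ~2.4 Hz bins, to resolve 30–70 Hz subharmonic
components), one-sided, magnitudes scaled by 2/Σw so a unit sinusoid peaks
near 1; frames extending past the signal are dropped rather than
zero-padded.

All detector thresholds are package defaults tuned on synthetic material —
they are implementation decisions, not measured constants — and are
arguments on every call:

* **Subharmonics:** per frame the dominant peak f₁ in 20–2000 Hz is found;
  order k (2…4) fires when a local peak within 1.5 bins of f₁/k exceeds 5 %
  of the f₁ magnitude and 5× the frame's median magnitude. Consecutive
  detections (≥ 2 frames) merge into events.
* **Frequency jumps:** a step in the fo track requires flanking 100 ms
  medians differing by ≥ 5 Hz, a two-level step model out-fitting a linear
  ramp over the same window (this is what rejects glissandi), and the track
  crossing the middle half of the step within 50 ms.
* **Biphonation:** the two strongest prominent narrowband peaks (second
  ≥ 10 % of first) whose ratio is not within 2 % of any p/q with
  p, q ≤ max_order flag a frame; ≥ 3 consecutive flagged frames with
  component frequencies stable to 2 % become an event. The default
  max_order 6 (7 where n:1 locks up to 7:1 are themselves in play) keeps
  golden-ratio pairs incommensurate: the nearest admissible fraction, 5/3,
  misses 1.618 by ~3 %. Broadband chaotic material fails the
  narrowband-persistence requirement.
* **Periodicity index:** per non-overlapping window, the maximum of the
  normalised autocorrelation at lags from one expected period to half the
  window. Pure pulse trains sit above 0.9, white noise below 0.05 in
  practice (bounded < 0.3 in tests), chaotic scenes in between but reliably
  below matched locked scenes.

## Phase synchrony

The pointwise statistic is cos(|Δphase|) of the two analytic signals (means
removed before the Hilbert transform; no unwrapping is needed since only
differences mod 2π matter). It is exactly symmetric in its arguments and
invariant to positive rescaling of either input.

Windowing: Nwin = floor(Fs/fo_min) — floor because the quotient is
generally non-integer — with fo_min = 0.2·min(fo_iEGG, fo_audio) for
group-1 material and 20 Hz for group 2 (Nwin = 1000 samples at 20 kHz).
Windows are non-overlapping by default (hop configurable). The first and
last 2 % of samples are excluded from window statistics to avoid Hilbert
edge artefacts; a window keeps its summary only if at least half its
samples are usable. Windows where either channel's RMS is below 10⁻⁸ of
its peak are reported missing (NaN), never zero — a PS of 0 is a meaningful
value (quadrature or integer ratio) and must not be conflated with
"undefined".

Band-passing is opt-in: a zero-phase 4th-order Butterworth
(forward–backward) applied to the *input signals* before the Hilbert
transform, with `default_band(fo_min, fo_est)` = [0.5·fo_min, 10·fo_est]
as the suggested band; an alternative mode low-passes the PS series itself
(`filter_ps_series=True`). Which quantity to filter is genuinely open; the
input-side default is the choice here because filtering the inputs keeps
the analytic-signal phase interpretable. The analysis scripts narrow the
band to [0.5, 1.5]·fo_supraglottic when comparing iEGG with SAW during n:1
entrainment, so the comparison runs on the fundamental the two channels
share — full-band PS of a 2:1 pair correctly centres near 0 (the
integer-ratio case), which is informative but not the in-phase question.

## Ratio and regime classification

`estimate_ratio` uses task means of voiced fo over the interval (≥ 50 %
voicing required on both tracks), snaps to the nearest integer n ≤ 8, and
scores confidence as (1 − residual/0.08)·(1 + 5·Σcv)⁻¹ — zero at or beyond
8 % relative residual, which separates 2:1 from 3:2 at these frequency
scales, and discounted by the coefficients of variation of both tracks.
Orientation is glottal over supraglottic; if the raw ratio is below 1 the
reciprocal is snapped and the orientation flagged, so swapping the inputs
is consistent. Incommensurate (golden-ratio) pairs land ~0.19 from the
nearest integer and therefore at confidence 0.

`classify_group`: group 1 iff mean periodicity index ≥ 0.7 and ratio
confidence ≥ 0.6 (both thresholds chosen on synthetic fixtures and
configurable); otherwise group 2, split into 2a/2b purely by the
`glottis_visible` input flag, since visibility is an endoscopic judgement.
For ratio-stepping glissandi the regime scripts use the best per-window
confidence from `track_ratio` as the entrainment evidence: a glide through
2:1 → 3:1 is entrained in its stable windows even though the whole-task
mean ratio is non-integer.

## Problem sizes

Synthetic study scenes are 2 s at 20 kHz; statistical checks use 0.8–1 s
scenes (ratio recovery: 50 seeds × n ∈ {1…7} at 20 dB SNR; detector
false-positive control: 100 clean entrained scenes on the glottal channel;
white-noise periodicity bound: 100 seeds × 20 000 samples). Rendered
stacks in tests and scripts are 40–160 frames, ample for whole supraglottic
cycles at 20 000 fps.

## Limitations

* The generator produces kinematic signals, not aerodynamic or
  tissue-mechanical ones: no source–filter interaction, no mucosal wave,
  no perceptual realism in the audio mix. Passing tests demonstrate that
  the measurement chain recovers known structure, not that real recordings
  satisfy the generator's assumptions (stationary noise, clean region
  brightness separation, simultaneous triggering).
* Segmentation assumes the open regions are separable from tissue by a
  global threshold after contrast adjustment; in-vivo material with
  specular highlights or motion blur will need per-recording profile
  tuning, and the video-enhancement preprocessing used in some HSV
  workflows is out of scope.
* The fo estimator is plain YIN with smoothing rather than a full
  probabilistic-threshold/Viterbi variant behind the same interface;
  on clean-to-moderate-SNR material the behaviour is equivalent for the
  statistics reported here.
* Chaos is asserted operationally (autocorrelation, periodicity index) —
  no Lyapunov exponents or correlation dimensions are computed.
* Only n:1 ratios are classified; general p:q locking is out of scope.
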