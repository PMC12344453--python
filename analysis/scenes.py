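"""Shared roster of synthetic voice-quality scenes used by the analysis
scripts.

Each entry emulates one of the irregular phonation qualities studied:
the entrained qualities (group 1) lock glottal and supraglottic
oscillators at integer ratios — constant for Undertone-like (2:1, with
period-doubling modulation and a small frequency jump into the quality)
and Distortion-like (2:1 at a higher rate), ratio-stepping through a
glissando for Growl-like (2:1 -> 3:1 over a fixed ~77 Hz supraglottic
oscillator) and Rattle-like (4:1 -> 7:1) — while the irregular qualities
(group 2) use drifting or chaotic coupling.  Frequencies follow the
in-vivo values reported for these qualities (glottal 44-280 Hz range,
supraglottic ~55-80 Hz).
"""

import math

from phonosync.synth import (CouplingSpec, FoTrajectory, OscillatorSpec,
                             SceneSpec)

# Supraglottic cycle phase relative to the glottal cycle for the entrained
# qualities.  A quarter-cycle offset places the supraglottic opening maximum
# on the undamped glottal pulse, emulating the in-vivo observation that the
# iEGG and SAW signals peak together (in-phase) during stable phonation.
IN_PHASE_OFFSET = math.pi / 2

FS = 20_000.0
DURATION = 2.0


def roster(seed: int = 0) -> dict[str, SceneSpec]:
    return {
        "undertone_like": SceneSpec(
            glottal=OscillatorSpec(fo=FoTrajectory.constant(136.0)),
            coupling=CouplingSpec(ratio_n=2, subharmonic_depth=0.4,
                                  phase_offset=IN_PHASE_OFFSET),
            duration=DURATION, fs=FS, seed=seed,
            events=[{"time": 0.9, "kind": "frequency_jump", "to_hz": 137.0}]),
        "undertone_onset_jump": SceneSpec(
            # clear phonation at 128 Hz jumping to 137 Hz at quality onset
            glottal=OscillatorSpec(fo=FoTrajectory.step(128.0, 137.0, 1.0)),
            coupling=CouplingSpec(ratio_n=2, subharmonic_depth=0.4,
                                  phase_offset=IN_PHASE_OFFSET),
            duration=DURATION, fs=FS, seed=seed + 1),
        "distortion_like": SceneSpec(
            glottal=OscillatorSpec(fo=FoTrajectory.constant(216.0)),
            coupling=CouplingSpec(ratio_n=2, subharmonic_depth=0.3,
                                  phase_offset=IN_PHASE_OFFSET),
            duration=DURATION, fs=FS, seed=seed + 2),
        "growl_like": SceneSpec(
            # 154 -> 231 Hz: exact 2:1 and 3:1 locks over the 77 Hz oscillator
            glottal=OscillatorSpec(fo=FoTrajectory.glissando(154.0, 231.0, 0.5, 1.5)),
            supraglottic=OscillatorSpec(fo=FoTrajectory.constant(77.0),
                                        open_quotient=0.72),
            coupling=CouplingSpec(ratio_n=2),
            duration=DURATION, fs=FS, seed=seed + 3),
        "rattle_like": SceneSpec(
            # 288 -> 504 Hz: exact 4:1 and 7:1 locks over the 72 Hz oscillator
            glottal=OscillatorSpec(fo=FoTrajectory.glissando(288.0, 504.0, 0.5, 1.5)),
            supraglottic=OscillatorSpec(fo=FoTrajectory.constant(72.0),
                                        open_quotient=0.72),
            coupling=CouplingSpec(ratio_n=4),
            duration=DURATION, fs=FS, seed=seed + 4),
        "vocal_fry_like": SceneSpec(
            glottal=OscillatorSpec(fo=FoTrajectory.constant(44.0)),
            coupling=CouplingSpec(ratio_n=1, regime="drifting"),
            duration=DURATION, fs=FS, seed=seed + 5),
        "death_growl_like": SceneSpec(
            glottal=OscillatorSpec(fo=FoTrajectory.constant(97.0)),
            coupling=CouplingSpec(ratio_n=1, regime="chaotic", noise_snr_db=25.0),
            duration=DURATION, fs=FS, seed=seed + 6),
        "biphonic": SceneSpec(
            glottal=OscillatorSpec(fo=FoTrajectory.constant(127.0)),
            coupling=CouplingSpec(ratio_n=1, regime="biphonation"),
            duration=DURATION, fs=FS, seed=seed + 7),
    }


# endoscopic-judgement flag per quality (2b = glottis hidden by constriction)
GLOTTIS_VISIBLE = {
    "undertone_like": True, "undertone_onset_jump": True,
    "distortion_like": True, "growl_like": True, "rattle_like": True,
    "vocal_fry_like": True, "death_growl_like": False, "biphonic": False,
}
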