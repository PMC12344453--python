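import numpy as np
import pytest

from phonosync import (CouplingSpec, FoTrajectory, OscillatorSpec, SceneSpec,
                       Signal, make_coupled_scene)

FS = 20_000.0


def sine(freq: float, duration: float = 1.0, fs: float = FS, phase: float = 0.0,
         label: str = "other") -> Signal:
    t = np.arange(int(round(duration * fs))) / fs
    return Signal(np.sin(2 * np.pi * freq * t + phase), fs=fs, label=label)


def locked_scene(fo: float = 136.0, n: int = 2, duration: float = 1.0,
                 seed: int = 0, snr_db: float | None = None,
                 subharmonic_depth: float = 0.0, regime: str = "locked",
                 **scene_kw) -> SceneSpec:
    return SceneSpec(
        glottal=OscillatorSpec(fo=FoTrajectory.constant(fo)),
        coupling=CouplingSpec(ratio_n=n, regime=regime,
                              subharmonic_depth=subharmonic_depth,
                              noise_snr_db=snr_db),
        duration=duration, fs=FS, seed=seed, **scene_kw)


@pytest.fixture(scope="session")
def undertone_scene():
    """A 2:1 entrained scene with period-doubling modulation, no noise."""
    rec, gt = make_coupled_scene(locked_scene(fo=136.0, n=2, duration=1.5,
                                              subharmonic_depth=0.4))
    return rec, gt


@pytest.fixture
def fs():
    return FS
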