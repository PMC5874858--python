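import numpy as np
import pytest

from scintqa import (BC408, BeamSpec, MaterialStack, QuenchModel,
                     simulate_depth_curves)
from scintqa.synthetic_data import NoiseSpec, ScenePhantom, render_scene

KB_STUDY = 0.154  # mm/MeV, the study's fitted Birks constant


@pytest.fixture(scope="session")
def sim60():
    """One shared 60 MeV transport run (moderate statistics)."""
    beam = BeamSpec(n_protons=30_000, rng_seed=1)
    return simulate_depth_curves(beam, MaterialStack([(BC408, 100.0)]))


@pytest.fixture(scope="session")
def sim60_det():
    """Deterministic 60 MeV run: no energy spread, straggling or attenuation."""
    beam = BeamSpec(energy_sigma=0.0, n_protons=200, rng_seed=2)
    return simulate_depth_curves(beam, MaterialStack([(BC408, 100.0)]),
                                 straggling=False, nuclear_attenuation=False)


@pytest.fixture(scope="session")
def scene60(sim60):
    """One rendered synthetic scene with study-like noise."""
    dose, let = sim60
    phantom = ScenePhantom(beam=BeamSpec(n_protons=30_000, rng_seed=1),
                           rng_seed=41)
    return render_scene(phantom, truth=(dose, let))


@pytest.fixture(scope="session")
def scene60_clean(sim60):
    """Noise-free, blur-free, artifact-free rendering of the same truth."""
    dose, let = sim60
    phantom = ScenePhantom(beam=BeamSpec(n_protons=30_000, rng_seed=1),
                           rng_seed=42, noise=NoiseSpec(0, 0, 0),
                           psf_sigma_px=0.0, tail_amplitude=0.0,
                           vignetting_strength=0.0)
    return render_scene(phantom, truth=(dose, let))
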