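import warnings

import numpy as np
import pytest

import agescore as ag

# the generator warns when wells hold < 20 cells etc.; tests that assert on
# warnings do so explicitly
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def foci_scene():
    """One well with planted DNA-damage foci (aged arm, rate 6)."""
    eff = ag.MarkerEffectSpec("gamma_h2ax", "foci_rate", 0.8, 6.0, dispersion=0.15)
    return ag.generate_scene(20, eff, seed=7, condition="+DOX")


@pytest.fixture(scope="session")
def intensity_scene_noiseless():
    """Noise-free nuclear-marker scene for exact ground-truth checks."""
    geom = ag.SceneGeometry(noise_sigma=1e-12)
    eff = ag.MarkerEffectSpec("mk", "channel_intensity", 50.0, 50.0, dispersion=0.1)
    return ag.generate_scene(20, eff, seed=5, geometry=geom), geom
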