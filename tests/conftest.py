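import numpy as np
import pytest

from fdbseg import FDBParams, SynthSpec, make_fingerprint


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def default_params():
    return FDBParams()


@pytest.fixture
def small_params():
    """Reduced orientation count / order for fast unit-level checks."""
    return FDBParams(L=4, n=4, gamma=2, pad=5)


@pytest.fixture
def clean_fingerprint():
    """Noise-free curved ridge pattern with its exact ground-truth ellipse."""
    spec = SynthSpec(seed=11, wavelength=12.0, orientation_field="concentric", noise_sigma=0.0)
    return make_fingerprint(spec)


@pytest.fixture
def lowquality_fingerprint():
    """The frozen hard fixture: noise plus ghost print, structure noise and
    dry breaks, used for the synthesis-strategy comparison."""
    spec = SynthSpec(
        seed=0,
        wavelength=8.0,
        orientation_field="concentric",
        noise_sigma=0.08,
        artifacts={
            "ghost_print": {"attenuation": 0.6},
            "structure_noise": {"strength": 0.15},
            "dry_breaks": {"prob": 0.3},
        },
    )
    return make_fingerprint(spec)
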