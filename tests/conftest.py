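import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from icseg import SynthSpec, build_geometry, rgb_to_luv, synth_image


@pytest.fixture(scope="session")
def default_frame():
    """One generator-default frame: (rgb uint8, ground-truth mask, spec)."""
    spec = SynthSpec(rng_seed=7)
    image, mask = synth_image(spec)
    return image, mask, spec


@pytest.fixture(scope="session")
def default_luv(default_frame):
    image, _, spec = default_frame
    geom = spec.geometry()
    return rgb_to_luv(image, field_mask=geom.field_mask(image.shape[:2])), geom


@pytest.fixture
def geom128():
    """17.4-mm field spanning a 128-px image (px_per_mm ~ 7.36)."""
    return build_geometry(17.4, 128, (128, 128))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
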