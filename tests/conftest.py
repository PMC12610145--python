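import numpy as np
import pytest

from aaaseg.phantom import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def clean_spec():
    """A deterministic-geometry phantom: no texture, blobs or jitter."""

    def _make(**overrides):
        defaults = dict(
            image_size=64,
            pixel_spacing_mm=1.5,
            vessel_diameter_mm=30.0,
            texture_sd=0.0,
            organ_blobs=(0, 0),
            diameter_jitter=0.0,
            background_level=0.3,
            seed=0,
        )
        defaults.update(overrides)
        return PhantomSpec(**defaults)

    return _make
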