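import numpy as np
import pytest

from glycoquant import simgen


@pytest.fixture(scope="session")
def small_spec() -> simgen.FieldSpec:
    """A 256x256 field with 5 cells — fast enough for per-test generation."""
    return simgen.FieldSpec(
        image_height=256,
        image_width=256,
        n_cells=5,
        cell_radius_range=(16.0, 22.0),
        nucleus_radius_range=(7.0, 10.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_scene(small_spec):
    """Noise-free rendered scene (DFC marker, +UV, 360 min)."""
    spec = small_spec.without_noise()
    return simgen.render_scene(simgen.sample_cell_layout(spec), spec)


@pytest.fixture(scope="session")
def noisy_scene(small_spec):
    return simgen.render_scene(simgen.sample_cell_layout(small_spec), small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
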