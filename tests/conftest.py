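import numpy as np
import pytest

from dosimix.grids import RoiMask, VolumeGrid
from dosimix.phantom import PhantomSpec, generate_phantom_case


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic tumor phantom at coarse resolution."""
    spec = PhantomSpec(
        shape=(24, 24, 16),
        spacing=(2.0, 2.0, 2.5),
        tumor_radius_mm=7.0,
        ptv_margin_mm=4.0,
        seed=42,
    )
    return generate_phantom_case(spec, case_id="fixture")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_grid(values, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(values, dtype=float), spacing)


def make_mask(values, spacing=(1.0, 1.0, 1.0), label="ROI"):
    return RoiMask(make_grid(values, spacing), label)
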