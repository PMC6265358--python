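import numpy as np
import pytest

from y90pet import PipelineConfig, run_phantom_acceptance
from y90pet.core_io import Mask, VoxelImage
from y90pet.synthetic import NoiseSpec, phantom_suite_specs, realize_case

PET_SPACING = (4.07, 4.07, 3.0)


@pytest.fixture
def make_image():
    """Factory for small constant images on a chosen grid."""

    def _make(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), value=0.0,
              origin=None, unit=""):
        if origin is None:
            origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
        return VoxelImage(values=np.full(shape, float(value)), spacing=spacing,
                          origin=origin, unit=unit)

    return _make


@pytest.fixture
def make_mask(make_image):
    """Factory for masks from boolean arrays (grid defaults to unit spacing)."""

    def _make(values, spacing=(1.0, 1.0, 1.0), origin=None):
        values = np.asarray(values, dtype=bool)
        grid = make_image(shape=values.shape, spacing=spacing, origin=origin)
        return Mask(values=values, grid=grid)

    return _make


@pytest.fixture(scope="session")
def phantom_report():
    """Full phantom-suite pipeline report at a fixed seed (shared: ~5 s)."""
    return run_phantom_acceptance(seed=1)


@pytest.fixture(scope="session")
def noiseless_suite():
    """The three bench phantoms blurred but noise-free (edge-profile oracles)."""
    specs = phantom_suite_specs(seed=0, noise=NoiseSpec(background_cov=0.0))
    return [realize_case(s, case_id=s.name, patient_id=s.name) for s in specs]


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()
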