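import numpy as np
import pytest

from fossa_gii.geometry_io import sample_la_interior
from fossa_gii.gii import score_field
from fossa_gii.kinematics import KinematicLimits, PivotFrame
from fossa_gii.synthetic import SyntheticConfig, make_fo_patch, make_geometry


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def geometry(default_cfg):
    return make_geometry(default_cfg)


@pytest.fixture(scope="session")
def patch(default_cfg, geometry):
    la, fo, thickness = geometry
    return make_fo_patch(default_cfg, fo, thickness)


@pytest.fixture(scope="session")
def la_samples(geometry):
    """Default-density interior sampling of the synthetic LA (~2k points)."""
    la, _, _ = geometry
    return sample_la_interior(la, spacing=2.5)


@pytest.fixture(scope="session")
def la_samples_coarse(geometry):
    """Coarse sampling for tests where density is irrelevant."""
    la, _, _ = geometry
    return sample_la_interior(la, spacing=5.0)


@pytest.fixture(scope="session")
def gii_field(patch, la_samples):
    return score_field(patch, la_samples)


@pytest.fixture(scope="session")
def limits():
    return KinematicLimits()


@pytest.fixture
def canonical_frame():
    """Pivot at the origin, insertion along +z, phi measured from +x."""
    return PivotFrame(
        origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]), ref=np.array([1.0, 0.0, 0.0])
    )
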