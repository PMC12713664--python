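import numpy as np
import pytest

from splash.hrf import StimulusTrain, build_basis, build_design
from splash.simulate import make_sphere_mesh
from splash.tps import ParcelGeometry, build_tprs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_design():
    """Two-condition block design, T=120, TR=1."""
    stims = [
        StimulusTrain("a", np.arange(0.0, 110.0, 60.0), np.full(2, 15.0)),
        StimulusTrain("b", np.arange(30.0, 110.0, 60.0), np.full(2, 15.0)),
    ]
    basis = build_basis("canonical", 1, 1.0)
    return build_design(stims, basis, 120, 1.0)


@pytest.fixture(scope="session")
def single_cond_design():
    stims = [StimulusTrain("a", np.arange(0.0, 110.0, 30.0), np.full(4, 15.0))]
    basis = build_basis("canonical", 1, 1.0)
    return build_design(stims, basis, 120, 1.0)


@pytest.fixture(scope="session")
def sphere_geom():
    return make_sphere_mesh(300, 6, seed=5)


@pytest.fixture(scope="session")
def parcel_2d():
    """A 2-D grid parcel with 30 locations."""
    xs, ys = np.meshgrid(np.arange(6.0), np.arange(5.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return ParcelGeometry("grid", np.arange(30), coords)


@pytest.fixture(scope="session")
def parcel_basis(parcel_2d):
    return build_tprs(parcel_2d, 8)
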