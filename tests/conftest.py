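import numpy as np
import pytest

from periquant.simulate import AcquisitionSpec, SceneSpec, Vessel


@pytest.fixture(scope="session")
def default_acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def small_acq() -> AcquisitionSpec:
    """A small, fast stack: 12 planes at 2 um, 64 x 64 pixels."""
    return AcquisitionSpec(shape_zyx=(12, 64, 64))


@pytest.fixture(scope="session")
def small_scene(small_acq) -> SceneSpec:
    """One straight mid-stack vessel in a small volume, low densities."""
    bz, by, bx = (
        n * v for n, v in zip(small_acq.shape_zyx, small_acq.voxel_size_zyx)
    )
    vessel = Vessel(points_um=((bz / 2, 0.0, bx / 2), (bz / 2, by, bx / 2)))
    return SceneSpec(
        bounds_zyx=(bz, by, bx),
        vessels=(vessel,),
        mural_density=8.0,
        fibroblast_density=4.0,
        seed=0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
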