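import numpy as np
import pytest

from filmetry.colorimetry import CameraModel
from filmetry.inversion import ParameterGrid, RGBTable, build_lut
from filmetry.optics import StackConfig, WavelengthGrid


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def air() -> StackConfig:
    return StackConfig()


@pytest.fixture(scope="session")
def silicon() -> StackConfig:
    return StackConfig.silicon()


@pytest.fixture(scope="session")
def camera8() -> CameraModel:
    return CameraModel(bit_depth=8)


@pytest.fixture(scope="session")
def coarse_grid() -> ParameterGrid:
    # Coarse enough that every node maps to a distinct 8-bit triplet in the
    # tested neighborhoods (no quantization plateaus), keeping tests exact.
    return ParameterGrid(t_min=0.0, t_max=1200.0, t_step=4.0,
                        n_min=1.33, n_max=1.55, n_step=4e-3)


@pytest.fixture(scope="session")
def coarse_lut_air(coarse_grid, air, camera8) -> RGBTable:
    return build_lut(coarse_grid, air, camera8)


@pytest.fixture(scope="session")
def default_lut_air(air, camera8) -> RGBTable:
    return build_lut(ParameterGrid(), air, camera8)


@pytest.fixture(scope="session")
def default_lut_silicon(silicon, camera8) -> RGBTable:
    return build_lut(ParameterGrid(), silicon, camera8)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
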