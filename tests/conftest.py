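import numpy as np
import pytest

from depspring.dielectrics import DielectricMaterial, Medium, ShelledCell
from depspring.spring import DeviceState


@pytest.fixture
def medium() -> Medium:
    return Medium(DielectricMaterial(relative_permittivity=78.5, conductivity=1.5))


@pytest.fixture
def midpoint_cell() -> ShelledCell:
    """Cell at the midpoint of every sampled parameter range."""
    return ShelledCell(
        outer_radius=5.0e-6,
        cytoplasm=DielectricMaterial(relative_permittivity=50.0, conductivity=0.7),
        membrane=DielectricMaterial(relative_permittivity=11.0, conductivity=5.05e-7),
    )


@pytest.fixture
def device(medium) -> DeviceState:
    return DeviceState(medium=medium)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_cell(rng: np.random.Generator) -> ShelledCell:
    """One cell drawn from the default sampling ranges (test-local helper)."""
    return ShelledCell(
        outer_radius=rng.uniform(2e-6, 8e-6),
        cytoplasm=DielectricMaterial(rng.uniform(20, 80), rng.uniform(0.2, 1.2)),
        membrane=DielectricMaterial(rng.uniform(2, 20), rng.uniform(10e-9, 1e-6)),
    )
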