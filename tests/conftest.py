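import numpy as np
import pytest
from hypothesis import settings

from platequant import data
from platequant.plate import PlateLayout, WellAddress, WellRole, layout_from_series

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_layout() -> PlateLayout:
    """Bundled layout: standards 0-20 μg/mL in row A, two triplicate samples."""
    return data.load_default_layout()


@pytest.fixture(scope="session")
def standards_layout() -> PlateLayout:
    """Five-standard calibration layout only (0, 5, 10, 15, 20 μg/mL)."""
    return layout_from_series([0, 5, 10, 15, 20])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def triplicate_layout(sample_id: str = "S1") -> PlateLayout:
    wells = {
        WellAddress("B", i + 1): WellRole("sample", sample_id=sample_id, replicate=i + 1)
        for i in range(3)
    }
    return PlateLayout(wells)
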