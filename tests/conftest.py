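import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bsamap import Arm, CrossDesign, WindowGrid

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def desk_design() -> CrossDesign:
    """Scaled-down cross for fast property tests: same structure as the
    full design, smaller population and fewer generations."""
    return CrossDesign(
        f1_per_reciprocal_sex=25,
        pop_size=120,
        generations=8,
        measured_females=60,
        tail_fraction=0.10,
    )


@pytest.fixture(scope="session")
def desk_grid() -> WindowGrid:
    arms = (Arm("2L", 23_000_000, 55.0), Arm("2R", 21_000_000, 52.0))
    return WindowGrid(arms, {"2L": 150, "2R": 130})


@pytest.fixture(scope="session")
def published_design() -> CrossDesign:
    return CrossDesign()


@pytest.fixture(scope="session")
def full_grid() -> WindowGrid:
    return WindowGrid.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
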