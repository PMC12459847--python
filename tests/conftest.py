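import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")

from esfringe.synthetic import (
    BundleArchetypeLibrary,
    LandscapeScenario,
    generate_landscape_pair,
    generate_villages,
)


@pytest.fixture(scope="session")
def small_scenario() -> LandscapeScenario:
    """A small, quick two-core landscape used across the unit tests."""
    return LandscapeScenario(
        grid_rows=16, grid_cols=16, refine_factor=8,
        n_cores=1, decay_length_cells=3.0,
        urban_radius_cells=2.5, fringe_radius_cells=5.0,
        water_fraction=0.06, n_poi=150, n_villages=24, seed=7,
    )


@pytest.fixture(scope="session")
def small_pair(small_scenario):
    return generate_landscape_pair(small_scenario)


@pytest.fixture(scope="session")
def small_villages(small_scenario):
    return generate_villages(small_scenario)


@pytest.fixture()
def archetype_library() -> BundleArchetypeLibrary:
    return BundleArchetypeLibrary(within_sd=0.05)
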