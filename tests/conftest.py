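import numpy as np
import pytest

from notoroot import PlantedTableSpec, SyntheticImageSpec, generate_feature_table


@pytest.fixture(scope="session")
def small_image_spec() -> SyntheticImageSpec:
    """A 128-px spec with proportionally scaled-down roots, for fast tests."""
    return SyntheticImageSpec(
        canvas=128,
        axis_mean=(72.0, 58.0, 46.0, 36.0),
        axis_sd=5.0,
    )


@pytest.fixture(scope="session")
def planted_table():
    """Default planted table: 5 informative + 35 noise, n=200."""
    return generate_feature_table(PlantedTableSpec(seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
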