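import numpy as np
import pytest

import allomed as am


@pytest.fixture(scope="session")
def fixture_schedule() -> dict[int, float]:
    """Per-year exponent schedule from the packaged annual fixture."""
    return {year: entry.exponent for year, entry in am.table2_fixture().items()}


@pytest.fixture(scope="session")
def noise_free_vertical_panel(fixture_schedule):
    config = am.SyntheticConfig(
        n_cities=41, exponents_by_year=fixture_schedule, noise_sd=0.0, seed=1
    )
    return am.generate_vertical_panel(config)


@pytest.fixture(scope="session")
def mixed_horizontal_panel():
    """41 cities, noise-free, 24 exponents in the positive range, 17 below."""
    rng = np.random.default_rng(2)
    b = np.concatenate([rng.uniform(0.9, 2.5, 24), rng.uniform(0.0, 0.8, 17)])
    config = am.SyntheticConfig(exponents_by_city=tuple(b), noise_sd=0.0, seed=2)
    return am.generate_horizontal_panel(config), b
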