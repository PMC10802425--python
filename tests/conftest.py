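import logging

import numpy as np
import pytest

from vagusmap import ElectrodeArray, SyntheticConfig, generate_cohort

# map-alignment warnings about empty groups are expected in cohort tests
logging.getLogger("vagusmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def array() -> ElectrodeArray:
    return ElectrodeArray()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic 5-animal cohort used across tests."""
    return generate_cohort(SyntheticConfig(n_animals=5, seed=11))


def all_spread(value: float) -> dict[str, float]:
    return {
        k: float(value)
        for k in (
            "cardiac",
            "recurrent_laryngeal",
            "pulmonary",
            "cardiopulmonary",
            "laryngopulmonary",
        )
    }
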