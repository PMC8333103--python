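import pandas as pd
import pytest

from canpancan.simulate import BreedSpec, SimConfig, simulate_germline


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=7, breeds=[BreedSpec("A"), BreedSpec("B")],
                     n_dogs_per_breed=10, n_shared_sites=150,
                     n_specific_per_breed=15)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_germline(small_config)


@pytest.fixture(scope="session")
def breed_labels(small_cohort):
    return pd.Series(
        small_cohort.truth.breed_of_dog.set_index("dog_id")["breed"])
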