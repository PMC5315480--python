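import pandas as pd
import pytest

from serpan import synthio


@pytest.fixture(scope="session")
def small_config() -> synthio.SimConfig:
    """Desk-scale population: 38 strains, ~500 genes, fast to simulate."""
    return synthio.SimConfig(
        seed=7, core_size=80, accessory_pool=400, snp_sites=200
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthio.simulate_population(small_config)


@pytest.fixture(scope="session")
def soil_labels(small_dataset) -> pd.Series:
    dataset, _ = small_dataset
    return dataset.strains.set_index("strain")["soil"]
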