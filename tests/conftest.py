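import pytest

from denovopost import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SimulationParams(
        n_unique=20,
        n_allele_pairs=6,
        n_merged_pairs=6,
        n_duplicate_pairs=5,
        n_alt_splice=6,
        n_chimera=3,
        n_female_only=3,
        n_male_only=3,
        n_junk_singletons=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)
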