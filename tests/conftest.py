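import numpy as np
import pytest

from aquamob.synthetic_data import SimulationConfig, generate_community

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


def mutate_seq(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    pos = np.where(rng.random(len(arr)) < rate)[0]
    for i in pos:
        arr[i] = [b for b in "ACGT" if b != arr[i]][rng.integers(0, 3)]
    return "".join(arr)


#: noise-free, reduced-size community used by most round-trip tests
SMALL_CONFIG = SimulationConfig(
    seed=11, n_wells=3, replicates_per_group=2,
    n_plasmid=6, n_phage=8, n_umge=10,
    plasmid_length_log_median=2000, phage_length_log_median=2500,
    umge_length_log_median=1800, length_log_sd=0.3,
    n_mags=8, mag_length=8000, host_link_rate=0.6, spacer_rate=0.3,
    term_planting_noise=0.0, n_contained_copies=3,
    n_core_mges=4, n_env_correlated=2,
)


@pytest.fixture(scope="session")
def small_community():
    return generate_community(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle(small_community):
    return small_community[0]


@pytest.fixture(scope="session")
def small_truth(small_community):
    return small_community[1]
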