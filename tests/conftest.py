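import numpy as np
import pytest

from lynchtrio import (
    SimulationConfig,
    default_catalog,
    simulate_germline_sites,
    simulate_reference,
    simulate_trio,
)


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def small_config():
    """A quick, fully exercised trio: losses in both tumors, noisy callers."""
    return SimulationConfig(
        seed=7,
        n_chromosomes=2,
        arm_length=60_000,
        het_sites_per_arm=400,
        n_somatic=120,
        lost_arms=(("rpc", "2p"), ("sic", "1p")),
        private_fp_rate=5.0,
        common_snp_fraction=0.1,
    )


@pytest.fixture(scope="session")
def small_trio(small_config):
    return simulate_trio(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        seed=11,
        n_chromosomes=2,
        arm_length=60_000,
        het_sites_per_arm=200,
        n_somatic=100,
        indel_fraction=0.0,
        caller_sensitivity=1.0,
        private_fp_rate=0.0,
        common_snp_fraction=0.0,
        lost_arms=(("rpc", "2p"),),
    )


@pytest.fixture(scope="session")
def noiseless_trio(noiseless_config):
    return simulate_trio(noiseless_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_reference():
    """Deterministic toy reference + arms shared by germline-site tests."""
    config = SimulationConfig(seed=3, n_chromosomes=1, arm_length=50_000, het_sites_per_arm=300)
    reference, arms = simulate_reference(config)
    return config, reference, arms
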