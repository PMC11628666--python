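import pytest
from hypothesis import HealthCheck, settings

import invex

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> invex.SimulationConfig:
    """A small but complete dataset: Table-1 design, planted effects, SNPs."""
    return invex.SimulationConfig(
        seed=11,
        n_autosomal_genes=80,
        n_z_genes=120,
        n_cis_de=10,
        n_trans_de=8,
        snp_density_per_mb=2.0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> invex.SimulatedDataset:
    return invex.simulate_dataset(small_config)
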