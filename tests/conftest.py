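import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mmib.synthgen import LatentClassGenConfig, gen_latent_class
from mmib.vmib import VMIBConfig, train_vmib

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def latent_data():
    """Dominant-modality multi-omics-like dataset (m1 > m2 redundant > m3 weak)."""
    return gen_latent_class(LatentClassGenConfig(n=2000, seed=0))


@pytest.fixture(scope="session")
def small_vmib_config():
    """Training configuration scaled to the synthetic problem size."""
    return VMIBConfig(
        latent_dim=16,
        hidden_units=64,
        epochs=60,
        lambda_compress=0.01,
        dropout_rate=0.1,
        seed=2,
    )


@pytest.fixture(scope="session")
def latent_model(latent_data, small_vmib_config):
    return train_vmib(latent_data, small_vmib_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
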