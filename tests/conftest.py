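import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from eivsdm.inference import InferenceConfig
from eivsdm.random_fields import FieldRealization, MaternParams, simulate_grf
from eivsdm.simulation import SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_misaligned():
    """Small misaligned dataset with measurement error (N=200, M=40)."""
    cfg = SimulationConfig(n_species=200, n_abiotic=40, misaligned=True,
                           measurement_error=True)
    return generate_dataset(cfg, run_seed=42)


@pytest.fixture(scope="session")
def tiny_aligned_noiseless():
    """Small aligned dataset without measurement error."""
    cfg = SimulationConfig(n_species=200, n_abiotic=40, misaligned=False,
                           measurement_error=False)
    return generate_dataset(cfg, run_seed=43)


@pytest.fixture
def fast_inference():
    """Short chains for structural tests (not used for accuracy claims)."""
    return InferenceConfig(n_warmup=100, n_draws=500, seed=7, n_field_draws=20)


@pytest.fixture(scope="session")
def noisy_field_obs():
    """Noisy observations of a known Matérn field at 60 points."""
    rng = np.random.default_rng(9)
    pts = rng.uniform(size=(60, 2))
    latent = simulate_grf(pts, MaternParams(variance=1.0, range=0.3), seed=11)
    noisy = latent.values + rng.normal(scale=np.sqrt(0.2), size=60)
    return FieldRealization(points=pts, values=noisy), latent
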