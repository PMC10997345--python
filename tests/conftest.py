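import numpy as np
import pytest

from larmex import (ModelSpec, SimConfig, reference_two_mood_spec,
                    simulate_dataset, stack_dataset)


@pytest.fixture
def spec() -> ModelSpec:
    """Reference two-mood network: self-loops +0.3, cross-inhibition -0.3,
    exogenous (+0.3, -0.3), G = 0.03 I, sigma2 = 0.02."""
    return reference_two_mood_spec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


@pytest.fixture
def noiseless_spec() -> ModelSpec:
    """Deterministic limit: no innovations, no random effects."""
    base = reference_two_mood_spec()
    return ModelSpec(k=2, beta_ar=base.beta_ar, beta_e=base.beta_e,
                     beta_c=base.beta_c, G=np.zeros((8, 8)), sigma2=0.0)


@pytest.fixture
def small_dataset(spec):
    """Six simulated days at the default design (10 prompts/day)."""
    return simulate_dataset(SimConfig(spec=spec, n_days=6, seed=42))


@pytest.fixture
def small_stacked(small_dataset):
    return stack_dataset(small_dataset)
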