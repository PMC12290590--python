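import numpy as np
import pytest

from invvae import (
    ModelConfig,
    SimulationConfig,
    TrainingConfig,
    simulate_cohort,
    train,
)


@pytest.fixture(scope="session")
def tiny_synthetic():
    """A small seeded synthetic cohort (n=60, V=10) shared across tests."""
    syn = simulate_cohort(SimulationConfig(n=60, V=10, seed=42))
    return syn


@pytest.fixture(scope="session")
def tiny_model(tiny_synthetic):
    """A briefly trained invariant model on the tiny cohort."""
    cohort = tiny_synthetic.to_cohort()
    mc = ModelConfig(V=10, K=4, C=1, R=3, encoder_hidden=(32, 16),
                     mapper_hidden=(16,), seed=0)
    tc = TrainingConfig(lambda_mi=1.0, batch_size=20, epochs=30, seed=1)
    model, history = train(cohort, mc, tc)
    return model, cohort, history


@pytest.fixture(scope="session")
def tiny_gate_model(tiny_synthetic):
    """A GATE (C=0, lambda=0) baseline trained on the same tiny cohort."""
    cohort = tiny_synthetic.to_cohort()
    mc = ModelConfig(V=10, K=4, C=0, R=3, encoder_hidden=(32, 16),
                     mapper_hidden=(16,), seed=0)
    tc = TrainingConfig(lambda_mi=0.0, batch_size=20, epochs=30, seed=1)
    model, history = train(cohort, mc, tc)
    return model, cohort, history


@pytest.fixture
def rng():
    return np.random.default_rng(7)
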