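"""Shared fixtures: encoder config, training batch, and trained replicates.

The replicate fixtures train the networks once per session (seeds 1-5)
and are shared by the behavioural and acceptance tests, which keeps the
suite runtime dominated by ten training runs rather than dozens.
"""

from __future__ import annotations

import numpy as np
import pytest

from neglectsim import (
    EncoderConfig,
    NetworkSpec,
    TrainingConfig,
    batch_encode,
    init_network,
    make_training_set,
    train_to_convergence,
)

SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def enc_config() -> EncoderConfig:
    return EncoderConfig()


@pytest.fixture(scope="session")
def training_batch(enc_config):
    return batch_encode(make_training_set(enc_config), enc_config)


@pytest.fixture(scope="session")
def training_config() -> TrainingConfig:
    return TrainingConfig()


def _train_replicates(spec: NetworkSpec, batch, config: TrainingConfig):
    out = {}
    for seed in SEEDS:
        net = init_network(spec, seed)
        net, trace = train_to_convergence(net, batch, config)
        out[seed] = (net, trace)
    return out


@pytest.fixture(scope="session")
def trained_specialized(training_batch, training_config):
    """Healthy RH-specialized networks, one per seed 1-5."""
    return _train_replicates(NetworkSpec.specialized(), training_batch, training_config)


@pytest.fixture(scope="session")
def trained_control(training_batch, training_config):
    """Healthy symmetric control networks, one per seed 1-5."""
    return _train_replicates(NetworkSpec.control(), training_batch, training_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
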