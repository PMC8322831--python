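import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from capstm.model import CapsTMModel, ModelConfig
from capstm.synthetic import make_worked_batch, worked_vocab


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_batch():
    return make_worked_batch()


@pytest.fixture
def tiny_config():
    """Smallest config that exercises every architectural component."""
    return ModelConfig(
        embedding_size=8,
        hidden_size=4,
        n_capsules=3,
        capsule_dim=5,
        routing_iters=3,
        max_len=6,
        conv_channels=4,
        conv_width=3,
        conv_dim=6,
        head_hidden=8,
        dropout_rate=0.0,
        seed=42,
    )


@pytest.fixture
def tiny_model(tiny_config):
    return CapsTMModel(tiny_config, worked_vocab())
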