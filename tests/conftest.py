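import numpy as np
import pytest

from dualdta.gnn_encoder import GnnConfig
from dualdta.model import DTAModel, ModelConfig, prepare_pairs
from dualdta.seq_encoder import EncoderConfig
from dualdta.synthetic import gen_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model_config():
    """Small but architecturally complete configuration for fast tests."""
    return ModelConfig(
        encoder=EncoderConfig(
            embed_dim=16, lstm_layers=1, heads=2, gem_groups=2, dropout=0.0
        ),
        gnn=GnnConfig(n_layers=2, hidden_dim=16, mlp_depth=2),
        head_hidden=16,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 records over 12 drugs x 6 targets."""
    return gen_dataset(12, 6, 0.85, seed=99)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_dataset):
    return prepare_pairs(tiny_dataset)


@pytest.fixture()
def tiny_model(tiny_model_config):
    return DTAModel(tiny_model_config, seed=3)


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of scalar-valued f with respect to x
    (mutated in place during probing)."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad
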