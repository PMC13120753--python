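import numpy as np
import pytest

from depfuse.fusion_model import FusionConfig, FusionModel
from depfuse.synthetic_data import GeneratorConfig, generate_cohort
from depfuse.training import (
    TrainConfig,
    encode_corpus,
    fit_encoders,
    stream_dims_from,
    train,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Twelve-session synthetic cohort shared across the suite."""
    cfg = GeneratorConfig(n_sessions=12, seed=42, n_utterances=10)
    sessions, manifest = generate_cohort(cfg)
    return sessions, manifest


@pytest.fixture(scope="session")
def tiny_encoders(tiny_cohort):
    sessions, _ = tiny_cohort
    train_sessions = [s for s in sessions if s.split == "train"]
    return fit_encoders(train_sessions, k=8, seed=42)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_cohort, tiny_encoders):
    sessions, _ = tiny_cohort
    codebooks, encoder = tiny_encoders
    data = {
        split: encode_corpus([s for s in sessions if s.split == split],
                             codebooks, encoder)
        for split in ("train", "dev", "test")
    }
    return data


@pytest.fixture(scope="session")
def tiny_trained(tiny_encoded, tiny_encoders):
    """A briefly trained model for evaluation-level tests."""
    codebooks, encoder = tiny_encoders
    config = FusionConfig(seed=42, stream_dims=stream_dims_from(codebooks, encoder))
    model = FusionModel(config)
    model, history = train(
        model, tiny_encoded["train"], tiny_encoded["dev"],
        TrainConfig(seed=42, learning_rate=1e-3, max_epochs=5),
    )
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
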