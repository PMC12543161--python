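import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_dataset():
    """30 class-separable phantom images (10 per class) with metadata."""
    from pneumofuzz.synth import gen_phantom_dataset

    return gen_phantom_dataset(n_per_class=10, size=32, seed=42)


@pytest.fixture(scope="session")
def trained_tiny(phantom_dataset):
    """A tiny capsule model fitted on the phantom set (shared: training is
    the slow part of the suite)."""
    from pneumofuzz.capsnet import TinyCapsNet, tiny_train

    images, labels, _ = phantom_dataset
    model = TinyCapsNet(seed=0)
    model, history = tiny_train(model, images, labels, epochs=50, lr=2e-3, seed=0)
    return model, history


@pytest.fixture()
def ranges():
    from pneumofuzz.confidence import load_symptom_ranges

    return load_symptom_ranges()


@pytest.fixture()
def rulebase():
    from pneumofuzz.fuzzy import RuleBase

    return RuleBase.default()
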