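import numpy as np
import pytest

from magpiefs import LabeledDataset, SyntheticSpec, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """Small separable dataset: feature 0 carries the classes, rest is noise."""
    spec = SyntheticSpec(
        n_samples=80, n_informative=1, n_redundant=0, n_noise=5,
        class_sep=4.0, seed=7,
    )
    data, truth = generate_synthetic(spec)
    return data, truth


@pytest.fixture
def tiny_split():
    """Hand-built 2-D train/test pair for KNN contract tests."""
    train = LabeledDataset(
        features=np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
        labels=np.array([0, 0, 1]),
        feature_names=["x", "y"],
        class_labels=["A", "B"],
    )
    test = LabeledDataset(
        features=np.array([[0.9, 1.0]]),
        labels=np.array([0]),
        feature_names=["x", "y"],
        class_labels=["A", "B"],
    )
    return train, test
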