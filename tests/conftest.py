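import numpy as np
import pytest

from mixedclust.datatypes import MixedDataset
from mixedclust.simulate import SimulationConfig, generate


@pytest.fixture
def three_cluster_data():
    """One seeded replicate of the standard 3-cluster mixed design."""
    data, labels = generate(SimulationConfig(seed=3))
    return data, labels


@pytest.fixture
def tiny_dataset():
    """A 6-record dataset small enough to reason about by hand."""
    X = np.array([[0, 1], [0, 1], [1, 1], [0, 0], [1, 0], [2, 1]])
    Z = np.array([[0.1, 5.0], [0.2, 5.5], [0.15, 5.2], [0.9, 1.0], [0.8, 1.2], [0.85, 0.9]])
    return MixedDataset(X=X, levels=[np.arange(3), np.arange(2)], Z=Z)
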