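import numpy as np
import pytest

from omibench.core import FeatureMatrix, LabelVector, MultiOmicsStudy
from omibench.simulate import SimulationSpec, SourceSpec, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 samples x 2 features with values 1..6 (row sums 3, 7, 11)."""
    return FeatureMatrix(
        np.arange(1.0, 7.0).reshape(3, 2), ["s1", "s2", "s3"], ["f1", "f2"], "tiny"
    )


@pytest.fixture
def small_study():
    """Balanced 40-sample, 2-source study with clear signal in source 1."""
    spec = SimulationSpec(
        n_samples=40,
        sources=[SourceSpec(30, 8, 2.5, name="informative"),
                 SourceSpec(25, 0, name="noise")],
        seed=7,
    )
    return generate_study(spec)


@pytest.fixture
def separable_study():
    """Strongly separable single-source study for classifier sanity checks."""
    spec = SimulationSpec(
        n_samples=100, sources=[SourceSpec(10, 5, 4.0, name="only")], seed=42
    )
    return generate_study(spec)


def random_weight_matrix(rng, n, density=1.0):
    """Symmetric non-negative weight matrix with zero diagonal."""
    A = rng.uniform(0, 1, size=(n, n))
    A *= rng.uniform(0, 1, size=(n, n)) < density
    W = np.triu(A, 1)
    W = W + W.T
    return W
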