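import numpy as np
import pytest

from betadce import FeatureMatrix, XorConfig, generate_xor


@pytest.fixture
def four_sample() -> FeatureMatrix:
    """Two tight same-class pairs far apart: every sample's E is 2/3."""
    return FeatureMatrix(
        values=np.array([[0.0], [1.0], [10.0], [11.0]]),
        labels=np.array(["A", "A", "B", "B"]),
        feature_names=("f1",),
    )


@pytest.fixture
def alternating() -> FeatureMatrix:
    """1-D lattice with alternating labels."""
    return FeatureMatrix(
        values=np.array([[0.0], [1.0], [2.0], [3.0]]),
        labels=np.array(["A", "B", "A", "B"]),
        feature_names=("f1",),
    )


@pytest.fixture(scope="session")
def xor_matrix() -> FeatureMatrix:
    return generate_xor(XorConfig(seed=0))


def random_matrix(rng: np.random.Generator, n: int, p: int) -> FeatureMatrix:
    """A random labeled matrix with at least two samples per class."""
    labels = np.array(["A", "A", "B", "B"] + list(rng.choice(["A", "B"], size=n - 4)))
    rng.shuffle(labels)
    return FeatureMatrix(
        values=rng.standard_normal((n, p)),
        labels=labels,
        feature_names=tuple(f"f{j}" for j in range(p)),
    )


def xor_with_noise(seed: int, n_noise: int = 8) -> FeatureMatrix:
    """XOR-like matrix with appended standard-normal noise features."""
    matrix = generate_xor(XorConfig(seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    for j in range(n_noise):
        matrix = matrix.with_feature(f"noise{j + 1}", rng.standard_normal(matrix.n_samples))
    return matrix
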