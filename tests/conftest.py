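import numpy as np
import pytest

from evobexpa import ExpressionMatrix, generate_background, plant_pattern


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A 30x8 random matrix with generic identifiers."""
    values = rng.uniform(0, 50, size=(30, 8))
    return ExpressionMatrix(values,
                            [f"g{i}" for i in range(30)],
                            [f"c{j}" for j in range(8)])


@pytest.fixture
def planted_case():
    """A 100x17 background with one perfect 20x10 planted pattern."""
    rng = np.random.default_rng(2024)
    matrix = generate_background(100, 17, rng=rng)
    truth = plant_pattern(matrix, 20, 10, rng)
    return matrix, truth


def random_pattern_submatrix(rng, size_i, size_j,
                             pi_range=(0.0, 10.0),
                             alpha_range=(0.5, 3.0),
                             beta_range=(-5.0, 5.0)):
    """A size_i x size_j matrix following b_ij = pi_i*alpha_j + beta_j."""
    pi = rng.uniform(*pi_range, size=size_i)
    alpha = rng.uniform(*alpha_range, size=size_j)
    beta = rng.uniform(*beta_range, size=size_j)
    return np.outer(pi, alpha) + beta[None, :]
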