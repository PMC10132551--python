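import numpy as np
import pytest

import covpcn as cp


@pytest.fixture(scope="session")
def three_points() -> cp.PatternMatrix:
    """The smallest hand-checkable dataset: mean (1/3, 1/3), 1/N covariance
    [[2/9, -1/9], [-1/9, 2/9]]."""
    return cp.PatternMatrix(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))


@pytest.fixture(scope="session")
def gaussian_patterns() -> cp.PatternMatrix:
    """A well-conditioned Gaussian memory set with N > d."""
    return cp.generate_gaussian_patterns(n=40, d=6, seed=11)


@pytest.fixture(scope="session")
def trained_recurrent(gaussian_patterns) -> cp.RecurrentParams:
    """Implicit network trained to tight convergence on the Gaussian set."""
    cfg = cp.TrainConfig(max_epochs=200_000, convergence_tol=1e-12)
    return cp.learn_recurrent(gaussian_patterns, cfg)


@pytest.fixture(scope="session")
def trained_explicit(gaussian_patterns) -> cp.ExplicitParams:
    cfg = cp.TrainConfig(max_epochs=200_000, convergence_tol=1e-11)
    return cp.learn_explicit(gaussian_patterns, cfg)


@pytest.fixture(scope="session")
def tight_infer() -> cp.InferConfig:
    return cp.InferConfig(max_iters=200_000, convergence_tol=1e-12)
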