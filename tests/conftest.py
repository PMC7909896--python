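import numpy as np
import pytest

from scbfl import Cohort, GradientSet, generate_cohort, init_model


@pytest.fixture
def tiny_cohort():
    """4-sample, 2-feature cohort with both classes present."""
    X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    return Cohort(features=X, labels=y)


@pytest.fixture
def small_cohort():
    return generate_cohort(
        n_samples=300, n_features=12, n_informative=6, base_log_odds=0.0,
        effect_scale=2.0, seed=11,
    )


@pytest.fixture
def fixture_gradient():
    """The worked 2-2-1 example: channel (0,0) has norm 5, channel (1,0) norm 12."""
    return GradientSet(
        deltas=[np.array([[3.0, 0.0], [4.0, 0.0]]), np.array([[0.0], [12.0]])]
    )


def random_gradient(rng, sizes):
    """GradientSet with entries ~ N(0, 1) for arbitrary layer sizes."""
    return GradientSet(
        deltas=[
            rng.normal(size=(sizes[l], sizes[l + 1]))
            for l in range(len(sizes) - 1)
        ]
    )


@pytest.fixture
def make_model():
    def _make(sizes, seed=0):
        return init_model(sizes, seed=seed)

    return _make
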