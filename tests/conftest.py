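import numpy as np
import pytest

import rankbag as rb


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_data():
    """Linearly separable two-feature fixture, train + test."""
    return rb.dominant_spec_toy(80, rng=11), rb.dominant_spec_toy(40, rng=12)


@pytest.fixture(scope="session")
def small_ensemble(toy_data):
    """A tiny trained ensemble: dominant linear spec vs a near-chance SVM.

    With gamma=1e6 the radial kernel degenerates to the identity matrix: the
    SVM memorizes the training rows and predicts only its bias class on new
    data, so LDA should win nearly every bootstrap.
    """
    train, _ = toy_data
    specs = (rb.make_spec("LDA"), rb.make_spec("SVM", gamma=1e6))
    config = rb.EnsembleConfig(specs=specs, n_bootstrap=15, seed=5)
    return rb.train_ensemble(train.X, train.y, config)


def random_problem(rng, m=None, k=None, max_m=6, max_k=4):
    """A random aggregation problem over letter identifiers."""
    m = m or int(rng.integers(2, max_m + 1))
    k = k or int(rng.integers(1, max_k + 1))
    items = [chr(ord("A") + i) for i in range(m)]
    lists = tuple(tuple(rng.permutation(items)) for _ in range(k))
    weights = tuple(float(w) for w in rng.uniform(0.1, 3.0, size=k))
    distance = "footrule" if rng.random() < 0.5 else "kendall"
    return rb.AggregationProblem(lists, weights, distance)
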