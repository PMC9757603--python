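import numpy as np
import pytest

from ikweights import KinematicDataset, WeightVector, weighted_pseudo_inverse


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, n, m, weight_low=0.1):
    """A random full-row-rank Jacobian and valid weight vector."""
    while True:
        J = rng.standard_normal((m, n))
        w = WeightVector.from_values(rng.uniform(weight_low, 1.0, n))
        try:
            weighted_pseudo_inverse(J, w)
        except np.linalg.LinAlgError:
            continue
        return J, w


def consistent_dataset(rng, n=3, m=2, K=40, weights=None):
    """Dataset drawn from the weighted-IK model with known nominal weights."""
    w = WeightVector.from_values(weights if weights is not None else rng.uniform(0.2, 1.0, n))
    Q = np.empty((n, K))
    X = np.empty((m, K))
    Jarr = np.empty((K, m, n))
    for k in range(K):
        J, _ = random_instance(rng, n, m)
        J_sharp = weighted_pseudo_inverse(J, w)
        x = rng.standard_normal(m)
        qd = J_sharp @ x
        Jarr[k] = J
        Q[:, k] = qd
        X[:, k] = J @ qd
    return KinematicDataset(Q, X, Jarr), w
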