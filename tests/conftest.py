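import numpy as np
import pytest

from hyperembed import (
    ModelParams,
    generate_network,
    sample_hidden_degrees,
    sample_uniform_sphere,
)
from hyperembed.inference import NetworkData, largest_component


def make_sd_network(seed, N=400, D=2, beta=4.0, gamma=2.7, mean_degree=8.0, communities=None,
                    cap_angle=0.7):
    """Synthetic S^D fixture restricted to its largest component.

    Returns ``(NetworkData, true_positions, hidden, kept_indices, net)``.
    """
    from hyperembed import generate_community_positions

    rng = np.random.default_rng(seed)
    hidden = sample_hidden_degrees(N, gamma, mean_degree, rng)
    labels = None
    if communities:
        positions, labels = generate_community_positions(N, D, communities, cap_angle, rng)
    else:
        positions = sample_uniform_sphere(N, D, rng)
    net = generate_network(hidden, positions, beta, D, mean_degree, rng,
                           community_labels=labels, cap_angle=cap_angle if communities else None)
    A, keep = largest_component(net.adjacency)
    return NetworkData.from_adjacency(A), positions[keep], hidden.kappa[keep], keep, net


@pytest.fixture(scope="session")
def s2_network():
    """One moderate S^2 network with ground truth, shared across tests."""
    return make_sd_network(seed=7, N=400, D=2, beta=4.0, gamma=2.7, mean_degree=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params_d2():
    return ModelParams.from_mean_degree(N=1000, D=2, beta=3.0, mean_degree=8.0)
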