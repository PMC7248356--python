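"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cannet import ExternalArrivals, GNetwork


def random_stable_network(seed: int, n: int = 4,
                          with_arrivals: bool = True) -> tuple[GNetwork, ExternalArrivals]:
    """A random small G-network guaranteed inside the product-form regime.

    Stability by construction: every neuron's external plus incoming
    excitatory rate stays below 80% of its firing rate.
    """
    rng = np.random.default_rng(seed)
    w_plus = rng.uniform(0.1, 1.0, (n, n))
    w_minus = rng.uniform(0.1, 1.0, (n, n))
    np.fill_diagonal(w_plus, 0.0)
    np.fill_diagonal(w_minus, 0.0)
    d = rng.uniform(0.0, 0.3, n)
    net = GNetwork(w_plus=w_plus, w_minus=w_minus, d=d, r_sink=np.ones(n))
    # scale arrivals so that Lambda_i + incoming_exc_i <= 0.8 * r_i
    from cannet import firing_rates

    r = firing_rates(net)
    inexc = w_plus.sum(axis=0)
    headroom = 0.8 * r - inexc
    if np.any(headroom <= 0):
        # scale all weights down until incoming excitation fits
        factor = float(np.min(0.7 * r / inexc))
        net = GNetwork(w_plus=w_plus * factor, w_minus=w_minus * factor,
                       d=d, r_sink=np.ones(n))
        r = firing_rates(net)
        headroom = 0.8 * r - net.w_plus.sum(axis=0)
    Lam = rng.uniform(0.0, 1.0, n) * np.maximum(headroom, 0.0)
    lam = rng.uniform(0.0, 0.5, n) if with_arrivals else np.zeros(n)
    arr = ExternalArrivals(Lambda=Lam if with_arrivals else np.zeros(n),
                           lambda_minus=lam)
    return net, arr


@pytest.fixture
def chain_network() -> tuple[GNetwork, ExternalArrivals]:
    """Two-neuron chain with known fixed point q = (0.5, 0.5)."""
    w_plus = np.array([[0.0, 1.0], [0.0, 0.0]])
    w_minus = np.zeros((2, 2))
    net = GNetwork(w_plus=w_plus, w_minus=w_minus, d=np.zeros(2),
                   r_sink=np.array([0.0, 1.0]))
    arr = ExternalArrivals(Lambda=np.array([0.5, 0.0]),
                           lambda_minus=np.zeros(2))
    return net, arr
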