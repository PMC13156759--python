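import numpy as np
import pytest

import teraflux as tf
from teraflux.network import apply_exchange_constraints


@pytest.fixture(scope="session")
def fig1_net():
    return tf.build_fig1_network()


@pytest.fixture(scope="session")
def fig1_constrained(fig1_net):
    """Toy loop network with the uptake of X fixed at 10."""
    return apply_exchange_constraints(fig1_net, tf.ExchangeConstraints(fixed={"v1": 10.0}))


@pytest.fixture(scope="session")
def uniform_weights(fig1_net):
    return tf.ReactionWeights(
        list(fig1_net.internal_ids), np.array([0.5, 0.5]), floor_value=1e-6, normalized=True
    )


@pytest.fixture(scope="session")
def fig1_solution(fig1_constrained, uniform_weights):
    return tf.solve(fig1_constrained, uniform_weights)


@pytest.fixture(scope="session")
def fig1_thermo(fig1_solution, fig1_constrained):
    return tf.potentials_from_duals(fig1_solution, fig1_constrained)


def solve_sampled(kind: str, seed: int, mode: str = "teraflux"):
    """Run the simulated-expression pipeline on a fixture network.

    Samples one fluxome, derives g = |v|, pins the sampled uptake as the
    measured exchange, and solves. Returns (net_constrained, sampled full
    vector, weights, solution).
    """
    spec = tf.FixtureSpec(kind=kind, seed=seed)
    net = tf.make_network(spec)
    sample = tf.sample_fluxomes(net, 1, spec)[0]
    weights = tf.expression_from_fluxes(net, sample)
    fixed = {}
    for k, rid in enumerate(net.exchange_ids):
        is_input = np.all(net.S_e[net.S_e[:, k] != 0, k] > 0)
        if is_input and net.ub_ex[k] - net.lb_ex[k] > 1e-12:  # pin free uptakes
            fixed[rid] = float(sample[net.n_internal + k])
    netc = apply_exchange_constraints(net, tf.ExchangeConstraints(fixed=fixed))
    sol = tf.solve(netc, weights, opts=tf.SolverOptions(mode=mode))
    return netc, sample, weights, sol
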