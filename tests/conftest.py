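"""Shared fixtures: networks, pools, and the brute-force inference oracle."""
from __future__ import annotations

import itertools

import numpy as np
import pytest

from citutor.network import build_default_network
from citutor.task_bank import generate_fixture_pool
from citutor.tutor import TutorConfig


@pytest.fixture()
def default_net():
    return build_default_network()


@pytest.fixture(scope="session")
def pool_small():
    """A 200-asset fixture pool, big enough for every task type."""
    return generate_fixture_pool(200, seed=7)


@pytest.fixture()
def tutor_cfg():
    return TutorConfig()


def enumerate_marginals(net):
    """Independent oracle: posterior marginals by full joint-state enumeration.

    Walks every joint state with explicit indexing (no tensor contraction),
    accumulating P(x) = Π CPT(x_node | parents) · Π ev(x_node) per state.
    """
    order = net.order
    axis = {n: i for i, n in enumerate(order)}
    k = len(order)
    idx = np.indices((3,) * k).reshape(k, -1).T
    p = np.ones(len(idx))
    for j, name in enumerate(order):
        node = net.nodes[name]
        p = p * net.evidence[name][idx[:, j]]
        if node.parents:
            cols = tuple(idx[:, axis[pp]] for pp in node.parents) + (idx[:, j],)
            p = p * net.cpts[name][cols]
    out = {}
    for j, name in enumerate(order):
        m = np.array([p[idx[:, j] == s].sum() for s in range(3)])
        out[name] = m / m.sum()
    return out


def enumerate_marginals_pure(net):
    """Same oracle in pure Python loops; only feasible for tiny networks."""
    order = net.order
    axis = {n: i for i, n in enumerate(order)}
    totals = {n: [0.0, 0.0, 0.0] for n in order}
    for states in itertools.product(range(3), repeat=len(order)):
        p = 1.0
        for j, name in enumerate(order):
            node = net.nodes[name]
            p *= net.evidence[name][states[j]]
            if node.parents:
                combo = tuple(states[axis[pp]] for pp in node.parents) + (states[j],)
                p *= net.cpts[name][combo]
        for j, name in enumerate(order):
            totals[name][states[j]] += p
    out = {}
    for name, t in totals.items():
        arr = np.array(t)
        out[name] = arr / arr.sum()
    return out


@pytest.fixture()
def enumeration_oracle():
    return enumerate_marginals
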