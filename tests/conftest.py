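"""Shared fixtures: small deterministic trees, random tree builders, and a
session-scoped pool of generated networks reused by the slower analyses."""

from __future__ import annotations

import numpy as np
import pytest

import vasctree as vt


def random_tree(rng: np.random.Generator, n_bif: int, with_hemo: bool = True) -> vt.Network:
    """Random geometric binary tree (not CCO-grown): split a random segment
    repeatedly.  Cheap structural test bed with valid geometry."""
    prox = [np.zeros(3)]
    dist = [rng.normal(size=3)]
    parent = [-1]
    children = {0: []}
    for _ in range(n_bif):
        candidates = [i for i, c in children.items() if not c]
        j = int(rng.choice(candidates))
        a, b = prox[j], dist[j]
        t = rng.uniform(0.25, 0.75)
        x = a + t * (b - a)
        m = len(parent)
        # distal piece
        prox.append(x.copy())
        dist.append(b.copy())
        parent.append(j)
        children[m] = []
        # new terminal
        tgt = x + rng.normal(scale=0.5, size=3)
        prox.append(x.copy())
        dist.append(tgt)
        parent.append(j)
        children[m + 1] = []
        dist[j] = x.copy()
        children[j] = [m, m + 1]
    net = vt.Network(np.array(prox), np.array(dist), np.array(parent))
    if with_hemo:
        vt.converge_diameters(net, vt.HemodynamicConfig())
        vt.propagate_hematocrit(net)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def demo_net():
    return vt.demo_network()


@pytest.fixture(scope="session")
def nets200():
    """Three generated shape-A networks with distinct seeds."""
    return [vt.generate(vt.GenerationConfig(n_bif=200, seed=s)) for s in (42, 43, 44)]


@pytest.fixture(scope="session")
def net200(nets200):
    """One generated control-shape network, 200 bifurcations."""
    return nets200[0]


@pytest.fixture(scope="session")
def nets700():
    """Paper-scale shape-A networks for the Horton/fractal reproduction."""
    return [vt.generate(vt.GenerationConfig(n_bif=700, seed=s)) for s in (101, 102, 103, 104, 105)]
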