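"""Shared fixtures and enumeration helpers."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import spgies as sp


def all_dags(n: int):
    """Every labelled DAG on ``n`` nodes (3^C(n,2) pair states, filtered)."""
    pairs = list(itertools.combinations(range(n), 2))
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        adj = np.zeros((n, n), dtype=np.int8)
        for (i, j), s in zip(pairs, states):
            if s == 1:
                adj[i, j] = 1
            elif s == 2:
                adj[j, i] = 1
        g = sp.DirectedGraph(adj)
        if sp.is_acyclic(g):
            out.append(g)
    return out


def random_dag(rng: np.random.Generator, n: int, p: float = 0.4) -> sp.DirectedGraph:
    adj = np.triu((rng.random((n, n)) < p).astype(np.int8), 1)
    perm = rng.permutation(n)
    return sp.DirectedGraph(adj[np.ix_(perm, perm)])


@pytest.fixture(scope="session")
def chain3() -> sp.DirectedGraph:
    return sp.DirectedGraph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def collider3() -> sp.DirectedGraph:
    return sp.DirectedGraph.from_edges(3, [(0, 2), (1, 2)])


@pytest.fixture(scope="session")
def ws10_benchmark():
    """10-node small-world benchmark instance (truth, SEM, 110-row dataset)."""
    return sp.make_benchmark("small_world", 10, {"k": 2, "p": 0.5}, n_obs=100, seed=42)


@pytest.fixture(scope="session")
def dags3():
    return all_dags(3)
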