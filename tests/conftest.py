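"""Shared fixtures and brute-force reference implementations."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest


def brute_force_mwcs(g: nx.Graph) -> tuple[float, tuple]:
    """Exhaustive maximum-weight connected induced subgraph (tiny graphs).

    Ties break toward the lexicographically smallest sorted node tuple,
    mirroring the solver's contract.
    """
    best_score, best_key = -np.inf, None
    nodes = list(g.nodes)
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if not nx.is_connected(g.subgraph(sub)):
                continue
            s = sum(g.nodes[n]["score"] for n in sub)
            key = tuple(sorted(sub))
            if s > best_score + 1e-12 or (
                abs(s - best_score) <= 1e-12 and (best_key is None or key < best_key)
            ):
                best_score, best_key = s, key
    return best_score, best_key


def all_partitions(nodes: list):
    """Every set partition of ``nodes`` (Bell-number many; keep n small)."""
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for p in all_partitions(rest):
        for i in range(len(p)):
            yield p[:i] + [p[i] + [first]] + p[i + 1 :]
        yield p + [[first]]


def partition_map(blocks: list) -> dict:
    return {v: i for i, blk in enumerate(blocks) for v in blk}


@pytest.fixture(scope="session")
def small_weighted_graphs() -> list[nx.Graph]:
    """Seeded suite of connected weighted graphs on 4-8 nodes."""
    rng = np.random.default_rng(2024)
    graphs = []
    while len(graphs) < 10:
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0 or not nx.is_connected(g):
            continue
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
        graphs.append(g)
    return graphs


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return g
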