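"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from mnalign import Network, SimilarityScores


def random_walkable_network(
    rng: np.random.Generator, n: int, p: float = 0.5, name: str = "N"
) -> Network:
    """Random connected, non-bipartite network (the simultaneous-walk
    product chain is then irreducible and aperiodic, so its stationary
    law is unique and power iteration converges)."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if (
            g.number_of_edges() > 0
            and nx.is_connected(g)
            and not nx.is_bipartite(g)
        ):
            break
    edges = []
    for u, v in g.edges():
        w = float(rng.uniform(0.5, 2.0))
        edges.append((f"{name}{u}", f"{name}{v}", w))
    return Network.from_edges(name, edges)


def random_similarity(
    rng: np.random.Generator, net_a: Network, net_b: Network, density: float = 0.4
) -> SimilarityScores:
    scores = {}
    for x in net_a.nodes:
        for y in net_b.nodes:
            if rng.random() < density:
                scores[(x, y)] = float(rng.uniform(0.1, 10.0))
    if not scores:
        scores[(net_a.nodes[0], net_b.nodes[0])] = 1.0
    return SimilarityScores(net_a.name, net_b.name, scores)


def product_chain_occupancy(tm_a, tm_b, sim, tol=1e-13, max_iter=200000):
    """Independent SMRW oracle: explicitly build the product transition
    matrix, find its stationary law by power iteration from uniform, and
    apply the semi-Markov occupancy law (stationary x holding time,
    renormalised over the similarity support)."""
    Ta = tm_a.trans.toarray()
    Tb = tm_b.trans.toarray()
    P = np.kron(Ta, Tb)
    n = P.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        nxt = pi @ P
        if np.abs(nxt - pi).max() < tol:
            pi = nxt
            break
        pi = nxt
    nb = len(tm_b.order)
    occ = {}
    for (x, y), h in sim.scores.items():
        occ[(x, y)] = pi[tm_a.index[x] * nb + tm_b.index[y]] * h
    total = sum(occ.values())
    return {k: v / total for k, v in occ.items()}


def brute_force_max_matching(weights: dict[tuple, float]) -> float:
    """Exhaustive maximum-weight bipartite matching over all one-to-one
    pairings of the support (small instances only)."""
    rows = sorted({r for r, _ in weights})
    cols = sorted({c for _, c in weights})
    best = 0.0
    k = min(len(rows), len(cols))
    for size in range(1, k + 1):
        for rsub in itertools.combinations(rows, size):
            for csub in itertools.permutations(cols, size):
                total = sum(weights.get((r, c), 0.0) for r, c in zip(rsub, csub))
                best = max(best, total)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def path_pair():
    """Two 3-node path graphs a-b-c and d-e-f with unit weights."""
    net_a = Network.from_edges("A", [("a", "b"), ("b", "c")])
    net_b = Network.from_edges("B", [("d", "e"), ("e", "f")])
    return net_a, net_b
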