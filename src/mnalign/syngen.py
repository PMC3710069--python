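"""Synthetic network families with known orthology.

Families of PPI-like networks are produced by evolving copies of a
common random ancestral network through duplication-based growth, one
copy per descendant species.  Three growth models are supported:

DMC (duplication-mutation-complementation)
    A random node is duplicated; each inherited neighbour edge is, with
    probability ``q_mod``, kept by exactly one of the two copies (chosen
    uniformly); the duplicate pair itself is connected with probability
    ``q_con``.
DMR (duplication with random mutation)
    A random node is duplicated with all its edges; each inherited edge
    is deleted with probability ``q_del``; the new node additionally
    attaches to every other node independently with probability
    ``q_new / N``.
CG (crystal growth)
    A new node attaches to a uniformly chosen anchor node and to each of
    the anchor's neighbours independently with probability ``p_attach``.

Every node carries the lineage id of the ancestral node it descends
from; nodes sharing a lineage across (or within) networks form one
ground-truth equivalence class, so the truth classes partition all
nodes.  Node-similarity scores emulating BLAST bit scores are drawn
from a heavy-right-tailed gamma law: ortholog pairs get a location
shift ``bias`` controlling how separated the ortholog and background
score distributions are; a sparse random fraction of non-ortholog pairs
receives a background score.

A resampling generator is also provided: replicate subnetworks grown
from hub seeds of a single parent network, with truth classes grouping
replicate nodes by shared parent node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .aligner import Alignment, EquivalenceClass, NodeRef
from .netio import Network, SimilarityScores


@dataclass
class ScoreModel:
    """Similarity-score law: gamma-distributed background, ortholog
    scores shifted right by ``bias`` (larger bias = cleaner separation);
    ``sparsity`` is the expected fraction of non-ortholog cross-network
    pairs that receive a background score at all."""

    bias: float = 100.0
    ortholog_shape: float = 2.0
    ortholog_scale: float = 25.0
    background_shape: float = 2.0
    background_scale: float = 25.0
    sparsity: float = 0.01

    def __post_init__(self):
        if self.bias < 0:
            raise ValueError(f"bias must be non-negative, got {self.bias}")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError(f"sparsity must be in [0, 1], got {self.sparsity}")


@dataclass
class NetworkFamily:
    """Networks plus ground-truth orthology and generation provenance."""

    networks: list[Network]
    lineages: dict[NodeRef, int]
    model: str
    params: dict
    seed: int
    truth: Alignment = field(init=False)

    def __post_init__(self):
        by_lineage: dict[int, set[NodeRef]] = {}
        for ref, lin in self.lineages.items():
            by_lineage.setdefault(lin, set()).add(ref)
        self.truth = Alignment(
            classes=[
                EquivalenceClass(members=members, id=lin)
                for lin, members in sorted(by_lineage.items())
            ]
        )

    def annotations(self) -> dict[NodeRef, str]:
        """Truth lineage labels doubling as functional-group annotations."""
        return {ref: f"fg{lin}" for ref, lin in self.lineages.items()}


DEFAULT_PARAMS = {
    "DMC": {"q_mod": 0.4, "q_con": 0.1},
    "DMR": {"q_del": 0.4, "q_new": 1.0},
    "CG": {"p_attach": 0.3},
}


def random_connected_graph(n: int, avg_degree: float, rng: np.random.Generator):
    """Random spanning tree plus uniformly random extra edges."""
    g = nx.Graph()
    g.add_node(0)
    for v in range(1, n):
        g.add_edge(v, int(rng.integers(v)))
    target_edges = max(n - 1, int(round(avg_degree * n / 2)))
    while g.number_of_edges() < target_edges:
        u, v = rng.integers(n, size=2)
        if u != v:
            g.add_edge(int(u), int(v))
    return g


def _grow_one(
    ancestor: nx.Graph,
    target_size: int,
    model: str,
    params: dict,
    rng: np.random.Generator,
) -> tuple[nx.Graph, dict[int, int]]:
    """Grow one descendant network; returns the graph (integer nodes)
    and the node -> ancestral lineage map."""
    g = ancestor.copy()
    lineage = {v: v for v in g.nodes}
    next_node = max(g.nodes) + 1
    while g.number_of_nodes() < target_size:
        existing = list(g.nodes)
        u = existing[int(rng.integers(len(existing)))]
        v = next_node
        next_node += 1
        if model == "DMC":
            g.add_node(v)
            for w in list(g.neighbors(u)):
                g.add_edge(v, w)
            for w in list(g.neighbors(u)):
                if w == v:
                    continue
                if rng.random() < params["q_mod"]:
                    loser = u if rng.random() < 0.5 else v
                    g.remove_edge(loser, w)
            if rng.random() < params["q_con"]:
                g.add_edge(u, v)
        elif model == "DMR":
            g.add_node(v)
            for w in list(g.neighbors(u)):
                if rng.random() >= params["q_del"]:
                    g.add_edge(v, w)
            p_new = params["q_new"] / g.number_of_nodes()
            for w in existing:
                if w != u and rng.random() < p_new:
                    g.add_edge(v, w)
        elif model == "CG":
            g.add_edge(v, u)
            for w in list(g.neighbors(u)):
                if w != v and rng.random() < params["p_attach"]:
                    g.add_edge(v, w)
        else:
            raise ValueError(f"unknown growth model {model!r}")
        lineage[v] = lineage[u]
    return g, lineage


def grow_family(
    model: str,
    ancestor_size: int,
    target_sizes: list[int],
    params: dict | None = None,
    seed: int = 0,
    ancestor_avg_degree: float = 5.0,
    names: list[str] | None = None,
) -> NetworkFamily:
    """Evolve one descendant network per target size from a common
    random connected ancestor, tracking ancestral lineages."""
    model = model.upper()
    if model not in DEFAULT_PARAMS:
        raise ValueError(f"unknown growth model {model!r}")
    if any(t < ancestor_size for t in target_sizes):
        raise ValueError("every target size must be >= ancestor_size")
    params = {**DEFAULT_PARAMS[model], **(params or {})}
    rng = np.random.default_rng(seed)
    ancestor = random_connected_graph(ancestor_size, ancestor_avg_degree, rng)
    if names is None:
        names = [f"net{i}" for i in range(len(target_sizes))]
    networks, lineages = [], {}
    for name, size in zip(names, target_sizes):
        g, lin = _grow_one(ancestor, size, model, params, rng)
        relabel = {v: f"n{v}" for v in g.nodes}
        nx.relabel_nodes(g, relabel, copy=False)
        nx.set_edge_attributes(g, 1.0, "weight")
        networks.append(Network(name, g))
        for v, anc in lin.items():
            lineages[(name, relabel[v])] = anc
    return NetworkFamily(
        networks, lineages, model,
        {**params, "ancestor_size": ancestor_size,
         "ancestor_avg_degree": ancestor_avg_degree,
         "target_sizes": list(target_sizes)},
        seed,
    )


def simulate_scores(
    family: NetworkFamily, sm: ScoreModel | None = None, seed: int = 0
) -> dict[frozenset, SimilarityScores]:
    """Draw one similarity table per unordered network pair: ortholog
    pairs (same truth class, different networks) get a bias-shifted
    ortholog score; a random ``sparsity`` fraction of the remaining
    cross-network pairs gets a background score; everything else is
    absent (score 0)."""
    sm = sm or ScoreModel()
    rng = np.random.default_rng(seed)
    nets = family.networks
    # lineage -> sorted member nodes, per network
    per_net: dict[str, dict[int, list[str]]] = {n.name: {} for n in nets}
    for (net, node), lin in family.lineages.items():
        per_net[net].setdefault(lin, []).append(node)
    for tab in per_net.values():
        for nodes in tab.values():
            nodes.sort()
    out: dict[frozenset, SimilarityScores] = {}
    for i, a in enumerate(nets):
        for b in nets[i + 1:]:
            scores: dict[tuple[str, str], float] = {}
            lin_a, lin_b = per_net[a.name], per_net[b.name]
            for lin in sorted(set(lin_a) & set(lin_b)):
                for x in lin_a[lin]:
                    for y in lin_b[lin]:
                        s = sm.bias + rng.gamma(
                            sm.ortholog_shape, sm.ortholog_scale
                        )
                        scores[(x, y)] = float(s)
            ortho = set(scores)
            nodes_a, nodes_b = a.nodes, b.nodes
            total = len(nodes_a) * len(nodes_b)
            n_bg = rng.binomial(total, sm.sparsity)
            ia = rng.integers(len(nodes_a), size=n_bg)
            ib = rng.integers(len(nodes_b), size=n_bg)
            draws = rng.gamma(sm.background_shape, sm.background_scale, size=n_bg)
            for k in range(n_bg):
                key = (nodes_a[ia[k]], nodes_b[ib[k]])
                if key in ortho or key in scores:
                    continue
                if draws[k] > 0:
                    scores[key] = float(draws[k])
            out[frozenset((a.name, b.name))] = SimilarityScores(
                a.name, b.name, scores
            )
    return out


def resample_subnetworks(
    parent: Network,
    count: int,
    min_size: int = 600,
    growth_fraction: float = 0.2,
    seed: int = 0,
) -> NetworkFamily:
    """Grow ``count`` replicate subnetworks of one parent network, each
    seeded at a random hub (top decile by weighted degree) and expanded
    by repeatedly absorbing a random ``growth_fraction`` of the current
    node set's outside neighbours until the size exceeds ``min_size``.
    Truth classes group replicate nodes sharing a parent node."""
    rng = np.random.default_rng(seed)
    g = parent.graph
    degrees = dict(g.degree(weight="weight"))
    ranked = sorted(degrees, key=lambda v: (-degrees[v], v))
    hubs = ranked[: max(1, len(ranked) // 10)]
    networks, lineages = [], {}
    parent_ids = {v: i for i, v in enumerate(g.nodes)}
    for r in range(count):
        name = f"rep{r}"
        current = {hubs[int(rng.integers(len(hubs)))]}
        while len(current) <= min_size:
            outside = sorted(
                {w for v in current for w in g.neighbors(v)} - current
            )
            if not outside:
                raise ValueError(
                    f"replicate {name}: growth stalled at {len(current)} "
                    f"nodes (< min_size={min_size})"
                )
            k = max(1, int(round(growth_fraction * len(outside))))
            picked = rng.choice(len(outside), size=min(k, len(outside)),
                                replace=False)
            current |= {outside[int(i)] for i in picked}
        sub = g.subgraph(current).copy()
        networks.append(Network(name, sub))
        for v in sub.nodes:
            lineages[(name, v)] = parent_ids[v]
    return NetworkFamily(
        networks, lineages, "RESAMPLE",
        {"min_size": min_size, "growth_fraction": growth_fraction,
         "count": count, "parent": parent.name},
        seed,
    )
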