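"""File formats and run configuration.

Everything downstream consumes only the in-memory types defined here:
:class:`Network` (one species' PPI graph), :class:`SimilarityScores`
(sparse cross-network node similarity, e.g. BLAST bit scores) and
:class:`RunConfig`.  Node IDs are opaque strings; internally a node is
always the pair ``(network name, node id)`` so identical IDs in different
networks never collide.  The ``net::node`` namespacing exists only in the
on-disk cluster format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import yaml

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input line (carries the offending line number)."""


class ValidationError(ValueError):
    """Semantically invalid input (unknown node, bad weight, ...)."""


@dataclass
class Network:
    """An undirected weighted interaction network.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is
    a declared node, all weights strictly positive (default 1.0).
    """

    name: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    def validate(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
            if w is None or w <= 0:
                raise ValidationError(f"non-positive weight on edge ({u!r}, {v!r})")

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from an edge iterable (weight defaults to 1.0)."""
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            u, v = e[0], e[1]
            w = float(e[2]) if len(e) > 2 else 1.0
            _add_edge_max(g, u, v, w)
        net = cls(name, g)
        net.validate()
        return net


def _add_edge_max(g: nx.Graph, u: str, v: str, w: float) -> bool:
    """Add an undirected edge, resolving duplicates by keeping the
    maximum weight (reliability-score semantics).  Returns False for
    self-loops, which are dropped."""
    if u == v:
        return False
    if g.has_edge(u, v):
        g.edges[u, v]["weight"] = max(g.edges[u, v]["weight"], w)
    else:
        g.add_edge(u, v, weight=w)
    return True


@dataclass
class SimilarityScores:
    """Sparse node-similarity table h(x, y) for one ordered network pair.

    Only strictly positive scores are stored.  ``transposed()`` gives the
    (b, a) view; both views expose the same underlying scores.
    """

    net_a: str
    net_b: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)

    def get(self, x: str, y: str) -> float:
        return self.scores.get((x, y), 0.0)

    def transposed(self) -> "SimilarityScores":
        return SimilarityScores(
            self.net_b, self.net_a, {(y, x): s for (x, y), s in self.scores.items()}
        )


@dataclass
class RunConfig:
    """Run parameters.

    alpha
        Balance between a pair's own alignment probability and its
        neighbourhood's in the intra-network consistency transform
        (1.0 = no neighbourhood influence).
    gamma
        Scaling factor of the coherence test used when inserting a node
        into an equivalence class that already holds nodes from the same
        network.
    max_per_net
        Cap on the number of nodes any single network may contribute to
        one equivalence class.
    top_fraction
        Quantile of transformed probabilities kept outside the original
        support by the sparsity filter of both consistency transforms.
    matching_normalizer
        Denominator of the network-homology weight: ``"min_size"``
        (default) divides the matching weight by min(|V_a|, |V_b|);
        ``"matching_size"`` divides by the matching cardinality.
    homology_stage
        Probability matrix stage on which homology weights are computed.
    ci_per_pair
        Conserved-interaction counting convention: once per network pair
        (default) or once globally per edge.
    """

    alpha: float = 0.9
    gamma: float = 0.8
    max_per_net: int = 10
    top_fraction: float = 0.01
    seed: int = 0
    matching_normalizer: str = "min_size"
    homology_stage: str = "intra"
    ci_per_pair: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValidationError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.max_per_net < 1:
            raise ValidationError(f"max_per_net must be positive, got {self.max_per_net}")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValidationError(
                f"top_fraction must be in (0, 1], got {self.top_fraction}"
            )
        if self.matching_normalizer not in ("min_size", "matching_size"):
            raise ValidationError(
                f"unknown matching_normalizer {self.matching_normalizer!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} is not a key/value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _parse_lines(path: str | Path, min_fields: int, max_fields: int):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not min_fields <= len(fields) <= max_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {min_fields}-{max_fields} "
                    f"whitespace-separated fields, got {len(fields)}: {line!r}"
                )
            yield lineno, fields


def read_network(path: str | Path, name: str) -> Network:
    """Read an edge list ("nodeA nodeB [weight]" per line, '#' comments).

    A line holding a single token declares an isolated node.  Missing
    weights default to 1.0.  Duplicate edges keep the maximum weight;
    self-loops are dropped (logged).
    """
    g = nx.Graph()
    dropped = 0
    for lineno, fields in _parse_lines(path, 1, 3):
        if len(fields) == 1:
            g.add_node(fields[0])
            continue
        u, v = fields[0], fields[1]
        if len(fields) == 3:
            try:
                w = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {fields[2]!r}") from exc
        else:
            w = 1.0
        if w <= 0:
            raise ValidationError(f"{path}:{lineno}: non-positive weight {w}")
        if not _add_edge_max(g, u, v, w):
            dropped += 1
    if dropped:
        logger.info("%s: dropped %d self-loop line(s)", path, dropped)
    return Network(name, g)


def write_network(network: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v, w in network.graph.edges(data="weight"):
            fh.write(f"{u}\t{v}\t{w:g}\n")
        for v in network.graph.nodes:
            if network.graph.degree(v) == 0:
                fh.write(f"{v}\n")


def read_similarity(path: str | Path, net_a: Network, net_b: Network) -> SimilarityScores:
    """Read "nodeA nodeB score" lines; zero/negative scores are dropped;
    unknown node IDs raise :class:`ValidationError`."""
    scores: dict[tuple[str, str], float] = {}
    nodes_a = set(net_a.graph.nodes)
    nodes_b = set(net_b.graph.nodes)
    for lineno, fields in _parse_lines(path, 3, 3):
        x, y, raw = fields
        if x not in nodes_a:
            raise ValidationError(
                f"{path}:{lineno}: node {x!r} not in network {net_a.name!r}"
            )
        if y not in nodes_b:
            raise ValidationError(
                f"{path}:{lineno}: node {y!r} not in network {net_b.name!r}"
            )
        try:
            s = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad score {raw!r}") from exc
        if s > 0:
            key = (x, y)
            scores[key] = max(scores.get(key, 0.0), s)
    return SimilarityScores(net_a.name, net_b.name, scores)


def write_similarity(sim: SimilarityScores, path: str | Path) -> None:
    with open(path, "w") as fh:
        for (x, y), s in sim.scores.items():
            fh.write(f"{x}\t{y}\t{s:g}\n")


def read_annotations(path: str | Path, network: Network) -> dict[tuple[str, str], str]:
    """Read "node<TAB>functional_group" lines for one network; nodes absent
    from the file stay unannotated."""
    groups: dict[tuple[str, str], str] = {}
    nodes = set(network.graph.nodes)
    for lineno, fields in _parse_lines(path, 2, 2):
        node, label = fields
        if node not in nodes:
            raise ValidationError(
                f"{path}:{lineno}: node {node!r} not in network {network.name!r}"
            )
        groups[(network.name, node)] = label
    return groups


def write_alignment(alignment, path: str | Path) -> None:
    """Write one equivalence class per line as tab-separated "net::node"
    tokens, largest classes first, lexicographic tie-break."""
    lines = []
    for cls_ in alignment.classes:
        tokens = sorted(f"{net}::{node}" for net, node in cls_.members)
        lines.append((-len(tokens), tokens))
    with open(path, "w") as fh:
        for _, tokens in sorted(lines):
            fh.write("\t".join(tokens) + "\n")


def read_alignment(path: str | Path):
    """Inverse of :func:`write_alignment`."""
    from .aligner import Alignment, EquivalenceClass

    classes = []
    for lineno, fields in _parse_lines(path, 1, 10**9):
        members = set()
        for token in fields:
            if "::" not in token:
                raise ParseError(f"{path}:{lineno}: token {token!r} lacks 'net::node'")
            net, node = token.split("::", 1)
            members.add((net, node))
        classes.append(EquivalenceClass(members=members, id=len(classes)))
    return Alignment(classes=classes)
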