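"""Greedy maximum-expected-accuracy alignment construction.

Candidate node pairs from all network pairs are visited in strictly
decreasing alignment probability (ties broken lexicographically so the
construction is fully deterministic).  Each pair either opens a new
equivalence class, inserts its free node into the class of its assigned
partner, or is skipped when both nodes are already placed.  Insertions
into a class that already holds nodes from the candidate's own network
must pass a coherence test: the candidate's mean probability against the
class's other-network members has to reach a fraction ``gamma`` of the
incumbents' average coherence.  A per-network cardinality cap bounds the
number of paralogs any class may absorb.  The exact formulation is a
maximum-weight n-partite matching (NP-hard), which this greedy pass
approximates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .netio import RunConfig
from .smrw import ProbMatrix

NodeRef = tuple[str, str]  # (network name, node id)


@dataclass
class EquivalenceClass:
    """A set of aligned nodes (putative orthologs) across networks."""

    members: set[NodeRef]
    id: int = 0

    def networks(self) -> set[str]:
        return {net for net, _ in self.members}

    def from_network(self, net: str) -> list[NodeRef]:
        return [m for m in self.members if m[0] == net]


@dataclass
class Alignment:
    """Disjoint equivalence classes plus an insertion provenance log."""

    classes: list[EquivalenceClass] = field(default_factory=list)
    provenance: list[tuple] = field(default_factory=list)

    def node_to_class(self) -> dict[NodeRef, EquivalenceClass]:
        mapping: dict[NodeRef, EquivalenceClass] = {}
        for cls_ in self.classes:
            for m in cls_.members:
                if m in mapping:
                    raise ValueError(f"node {m} appears in two classes")
                mapping[m] = cls_
        return mapping

    def induced_pairs(self) -> set[frozenset]:
        """All cross-network member pairs induced by the classes."""
        pairs = set()
        for cls_ in self.classes:
            members = sorted(cls_.members)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if a[0] != b[0]:
                        pairs.add(frozenset((a, b)))
        return pairs

    def total_nodes(self) -> int:
        return sum(len(c.members) for c in self.classes)


class _ProbLookup:
    """Symmetric probability lookup over all cross-transformed matrices."""

    def __init__(self, probs: dict[frozenset, ProbMatrix]):
        self._tables: dict[tuple[str, str], dict[tuple[str, str], float]] = {}
        for p in probs.values():
            self._tables[(p.net_a, p.net_b)] = p.to_dict()

    def get(self, x: NodeRef, y: NodeRef) -> float:
        (net_x, node_x), (net_y, node_y) = x, y
        tab = self._tables.get((net_x, net_y))
        if tab is not None:
            return tab.get((node_x, node_y), 0.0)
        tab = self._tables.get((net_y, net_x))
        if tab is not None:
            return tab.get((node_y, node_x), 0.0)
        return 0.0


def coherence_probability(x: NodeRef, cls: EquivalenceClass, probs) -> float:
    """Mean alignment probability of x against the class members drawn
    from networks other than x's own; absent sparse entries count 0."""
    if not isinstance(probs, _ProbLookup):
        probs = _ProbLookup(probs)
    others = [m for m in cls.members if m[0] != x[0] and m != x]
    if not others:
        raise ValueError(
            f"coherence of {x} undefined: class has only same-network members"
        )
    return sum(probs.get(x, m) for m in others) / len(others)


def greedy_mea_align(
    probs: dict[frozenset, ProbMatrix], config: RunConfig | None = None
) -> Alignment:
    """Build the multiple alignment greedily from alignment probabilities.

    Only strictly positive entries are candidates.  Singleton classes are
    dropped from the returned alignment.
    """
    config = config or RunConfig()
    lookup = _ProbLookup(probs)

    candidates = []
    for p in probs.values():
        for x, y, v in p.items():
            if v > 0:
                candidates.append((-v, p.net_a, x, p.net_b, y))
    candidates.sort()

    alignment = Alignment()
    assigned: dict[NodeRef, EquivalenceClass] = {}
    next_id = 0

    for negv, net_x, node_x, net_y, node_y in candidates:
        a: NodeRef = (net_x, node_x)
        b: NodeRef = (net_y, node_y)
        ca, cb = assigned.get(a), assigned.get(b)
        if ca is not None and cb is not None:
            alignment.provenance.append(("skip", a, b, -negv, "both assigned"))
            continue
        if ca is None and cb is None:
            cls_ = EquivalenceClass(members={a, b}, id=next_id)
            next_id += 1
            alignment.classes.append(cls_)
            assigned[a] = cls_
            assigned[b] = cls_
            alignment.provenance.append(("open", a, b, -negv, "new class"))
            continue
        free, cls_ = (a, cb) if ca is None else (b, ca)
        incumbents = cls_.from_network(free[0])
        if len(incumbents) >= config.max_per_net:
            alignment.provenance.append(("reject", free, cls_.id, -negv, "cap"))
            continue
        if incumbents:
            cand_coh = coherence_probability(free, cls_, lookup)
            incumbent_coh = sum(
                coherence_probability(m, cls_, lookup) for m in incumbents
            ) / len(incumbents)
            if cand_coh < config.gamma * incumbent_coh:
                alignment.provenance.append(
                    ("reject", free, cls_.id, -negv, "coherence")
                )
                continue
        cls_.members.add(free)
        assigned[free] = cls_
        alignment.provenance.append(
            ("insert", free, cls_.id, -negv,
             "coherence ok" if incumbents else "no incumbents")
        )

    alignment.classes = [c for c in alignment.classes if len(c.members) >= 2]
    return alignment


def pair_accuracy(predicted: Alignment, truth: Alignment) -> float:
    """Fraction of the truth's induced cross-network node pairs that the
    predicted alignment also induces."""
    truth_pairs = truth.induced_pairs()
    if not truth_pairs:
        raise ValueError("truth alignment induces no cross-network pairs")
    pred_pairs = predicted.induced_pairs()
    return len(truth_pairs & pred_pairs) / len(truth_pairs)
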