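"""Evaluation measures for multiple network alignments.

An equivalence class is *correct* when every annotated member carries
the same functional-group label.  Before computing the accuracy measures
(SPE, CN, MNE, sensitivity) the alignment is filtered: unannotated nodes
are removed from every class, then classes reduced to a single node are
dropped.  The interaction-conservation counts (CI/COI) and the coverage
histograms are computed on the unfiltered alignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from .aligner import Alignment, EquivalenceClass, NodeRef
from .netio import Network

logger = logging.getLogger(__name__)

AnnotationMap = dict[NodeRef, str]


@dataclass
class MetricsReport:
    """Flat bundle of every evaluation measure for one alignment."""

    spe: float = 0.0                 # % of pure classes
    cn: int = 0                      # nodes inside pure classes
    mne: float = 0.0                 # mean normalized entropy, in [0, 1]
    sensitivity: float = 0.0         # % of evaluated nodes inside pure classes
    ci: int = 0                      # conserved interactions
    coi: int = 0                     # conserved interactions between pure classes
    n_classes: int = 0
    class_coverage: dict[int, int] = field(default_factory=dict)
    node_coverage: dict[int, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "spe": self.spe, "cn": self.cn, "mne": self.mne,
            "mne_x100": 100.0 * self.mne, "sensitivity": self.sensitivity,
            "ci": self.ci, "coi": self.coi, "n_classes": self.n_classes,
        }
        for k, v in sorted(self.class_coverage.items()):
            d[f"class_coverage_{k}"] = v
        for k, v in sorted(self.node_coverage.items()):
            d[f"node_coverage_{k}"] = v
        return d


def filter_for_eval(alignment: Alignment, ann: AnnotationMap) -> Alignment:
    """Drop unannotated nodes, then classes left with fewer than 2 nodes."""
    classes = []
    for cls_ in alignment.classes:
        kept = {m for m in cls_.members if m in ann}
        if len(kept) >= 2:
            classes.append(EquivalenceClass(members=kept, id=cls_.id))
    return Alignment(classes=classes)


def _is_correct(cls_: EquivalenceClass, ann: AnnotationMap) -> bool:
    labels = {ann[m] for m in cls_.members if m in ann}
    return len(labels) == 1


def specificity_cn(alignment: Alignment, ann: AnnotationMap) -> tuple[float, int]:
    """SPE: percentage of classes whose members all share one functional
    group; CN: total node count over those pure classes."""
    if not alignment.classes:
        logger.warning("empty alignment: specificity undefined, reporting 0")
        return 0.0, 0
    correct = [c for c in alignment.classes if _is_correct(c, ann)]
    spe = 100.0 * len(correct) / len(alignment.classes)
    cn = sum(len(c.members) for c in correct)
    return spe, cn


def normalized_entropy(cls_: EquivalenceClass, ann: AnnotationMap) -> float:
    """Entropy of the class's label mixture divided by log(#distinct
    labels present); 0 for a pure class, 1 for a uniform mixture."""
    labels = [ann[m] for m in cls_.members if m in ann]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    d = len(counts)
    if d <= 1:
        return 0.0
    n = len(labels)
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return h / math.log(d)


def mean_normalized_entropy(alignment: Alignment, ann: AnnotationMap) -> float:
    if not alignment.classes:
        return 0.0
    return sum(normalized_entropy(c, ann) for c in alignment.classes) / len(
        alignment.classes
    )


def sensitivity(alignment: Alignment, ann: AnnotationMap) -> float:
    """Percentage of nodes (in the filtered alignment) sitting in pure
    classes; shares its numerator with CN."""
    total = alignment.total_nodes()
    if total == 0:
        logger.warning("empty alignment: sensitivity undefined, reporting 0")
        return 0.0
    _, cn = specificity_cn(alignment, ann)
    return 100.0 * cn / total


def _class_pair_edges(net: Network, members_by_class: dict[int, set[str]]):
    """Map (class id pair) -> set of edges of `net` whose endpoints land
    in that (unordered) class pair; the within-class case uses id==id."""
    node_cls: dict[str, int] = {}
    for cid, nodes in members_by_class.items():
        for v in nodes:
            node_cls[v] = cid
    spans: dict[tuple[int, int], set[frozenset]] = {}
    for u, v in net.graph.edges():
        cu, cv = node_cls.get(u), node_cls.get(v)
        if cu is None or cv is None:
            continue
        key = (min(cu, cv), max(cu, cv))
        spans.setdefault(key, set()).add(frozenset((u, v)))
    return spans


def conserved_interactions(
    alignment: Alignment,
    networks: list[Network],
    ann: AnnotationMap,
    per_pair: bool = True,
) -> tuple[int, int]:
    """Count conserved interactions (CI) and the subset between pure
    classes (COI).

    An edge of network u spanning class pair (C1, C2) is conserved w.r.t.
    network v when v has at least one edge spanning the same class pair.
    With ``per_pair`` (default) each conserved u-edge counts once per
    unordered network pair (u ordered before v by name); otherwise each
    u-edge counts at most once globally.
    """
    # key classes by position, not by their (possibly clashing) ids
    members_by_class = dict(enumerate(alignment.classes))
    per_net_spans = {}
    for net in networks:
        by_class = {
            cid: {node for n2, node in c.members if n2 == net.name}
            for cid, c in members_by_class.items()
        }
        per_net_spans[net.name] = _class_pair_edges(net, by_class)
    correct_ids = {
        cid for cid, c in members_by_class.items() if _is_correct(c, ann)
    }
    ci = coi = 0
    nets_sorted = sorted(networks, key=lambda n: n.name)
    conserved_global: set = set()
    for u, v in combinations(nets_sorted, 2):
        spans_u = per_net_spans[u.name]
        spans_v = per_net_spans[v.name]
        for key, edges_u in spans_u.items():
            if key not in spans_v:
                continue
            k = len(edges_u)
            if not per_pair:
                fresh = {(u.name, e) for e in edges_u} - conserved_global
                conserved_global |= fresh
                k = len(fresh)
            ci += k
            if key[0] in correct_ids and key[1] in correct_ids:
                coi += k
    return ci, coi


def coverage(
    alignment: Alignment, n_networks: int
) -> tuple[dict[int, int], dict[int, int]]:
    """Histogram of classes (and their nodes) by the number of distinct
    networks the class spans, k = 1 .. n_networks."""
    class_cov = {k: 0 for k in range(1, n_networks + 1)}
    node_cov = {k: 0 for k in range(1, n_networks + 1)}
    for cls_ in alignment.classes:
        k = len(cls_.networks())
        class_cov[k] += 1
        node_cov[k] += len(cls_.members)
    return class_cov, node_cov


def require_all_species(alignment: Alignment, n_networks: int) -> Alignment:
    """Keep only classes containing at least one node from every network."""
    return Alignment(
        classes=[c for c in alignment.classes if len(c.networks()) == n_networks]
    )


def evaluate(
    alignment: Alignment,
    networks: list[Network],
    ann: AnnotationMap,
    truth: Alignment | None = None,
    per_pair: bool = True,
) -> MetricsReport:
    """Compute the full report (accuracy measures on the filtered
    alignment; CI/COI and coverage on the unfiltered one)."""
    filtered = filter_for_eval(alignment, ann)
    spe, cn = specificity_cn(filtered, ann)
    report = MetricsReport(
        spe=spe,
        cn=cn,
        mne=mean_normalized_entropy(filtered, ann),
        sensitivity=sensitivity(filtered, ann),
        n_classes=len(alignment.classes),
    )
    report.ci, report.coi = conserved_interactions(
        alignment, networks, ann, per_pair=per_pair
    )
    report.class_coverage, report.node_coverage = coverage(
        alignment, len(networks)
    )
    return report
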