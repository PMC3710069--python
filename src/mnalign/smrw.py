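"""Semi-Markov random-walk correspondence scores and alignment probabilities.

A simultaneous random walk on two networks is a walk on their product
graph.  When the walker's mean holding time in product state (x, y) is
the node similarity h(x, y), the long-run fraction of time spent in
(x, y) — the semi-Markov occupancy law — is the product-chain stationary
probability times the holding time, renormalised.  For reversible walks
on undirected weighted graphs the product stationary law factorises into
the two weighted-degree laws, which gives a closed form over the sparse
similarity support; the dense product graph is never materialised.

The occupancy scores ("global correspondence scores") are then turned
into symmetric pairwise node alignment probabilities by averaging the
row- and column-normalised scores, balancing the relative importance of
x among the candidate matches of y and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .netio import Network, SimilarityScores


@dataclass
class TransitionModel:
    """Random-walk transition law of one network.

    ``trans`` is row-stochastic on non-isolated nodes
    (trans[x, x'] = w(x,x') / weighted degree of x); ``stat`` is the
    stationary law of the reversible walk, proportional to weighted
    degree.  Isolated nodes get an empty row and stationary mass 0.
    """

    network: Network
    order: list[str]
    index: dict[str, int]
    trans: sp.csr_matrix
    stat: np.ndarray


def build_transition_model(network: Network) -> TransitionModel:
    """Degree-proportional stationary law; weight-proportional transitions."""
    if network.n_edges == 0:
        raise ValueError(f"network {network.name!r} has no interactions")
    order = list(network.graph.nodes)
    index = {v: i for i, v in enumerate(order)}
    n = len(order)
    adj = nx_weighted_adjacency(network, order, index)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.zeros(n)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    trans = sp.diags(inv) @ adj
    stat = deg / deg.sum()
    return TransitionModel(network, order, index, trans.tocsr(), stat)


def nx_weighted_adjacency(network: Network, order, index) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for u, v, w in network.graph.edges(data="weight"):
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(order), len(order))
    )


@dataclass
class PairMatrix:
    """Sparse matrix over one ordered network pair, with node books."""

    net_a: str
    net_b: str
    nodes_a: list[str]
    nodes_b: list[str]
    mat: sp.csr_matrix
    index_a: dict[str, int] = field(repr=False, default_factory=dict)
    index_b: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index_a:
            self.index_a = {v: i for i, v in enumerate(self.nodes_a)}
        if not self.index_b:
            self.index_b = {v: i for i, v in enumerate(self.nodes_b)}

    def get(self, x: str, y: str) -> float:
        i, j = self.index_a.get(x), self.index_b.get(y)
        if i is None or j is None:
            return 0.0
        return self.mat[i, j]

    def items(self):
        coo = self.mat.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            yield self.nodes_a[i], self.nodes_b[j], v

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {(x, y): v for x, y, v in self.items() if v != 0}


@dataclass
class CorrespondenceMatrix(PairMatrix):
    """SMRW occupancy scores; entries sum to 1 over the similarity support."""


@dataclass
class ProbMatrix(PairMatrix):
    """Pairwise node alignment probabilities (entries in [0, 1]).

    ``stage`` records the processing step: raw (fresh from the SMRW
    scores), intra (after the intra-network consistency transform) or
    cross (after the cross-network transform).
    """

    stage: str = "raw"

    def transposed(self) -> "ProbMatrix":
        return ProbMatrix(
            self.net_b, self.net_a, self.nodes_b, self.nodes_a,
            self.mat.T.tocsr(), self.index_b, self.index_a, stage=self.stage,
        )


def similarity_csr(sim: SimilarityScores, tm_a: TransitionModel, tm_b: TransitionModel):
    rows, cols, vals = [], [], []
    for (x, y), s in sim.scores.items():
        rows.append(tm_a.index[x])
        cols.append(tm_b.index[y])
        vals.append(s)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(tm_a.order), len(tm_b.order))
    )


def correspondence_scores(
    tm_a: TransitionModel, tm_b: TransitionModel, sim: SimilarityScores
) -> CorrespondenceMatrix:
    """Occupancy of the simultaneous semi-Markov walk on the product graph.

    c(x, y) = stat_a(x) stat_b(y) h(x, y), renormalised over the
    similarity support.  Isolated nodes have stationary mass 0, so they
    are excluded from the walk automatically.
    """
    h = similarity_csr(sim, tm_a, tm_b)
    c = sp.diags(tm_a.stat) @ h @ sp.diags(tm_b.stat)
    c.eliminate_zeros()
    total = c.sum()
    if total <= 0:
        raise ValueError(
            f"no positive similarity on non-isolated nodes for pair "
            f"({sim.net_a!r}, {sim.net_b!r})"
        )
    c = (c / total).tocsr()
    return CorrespondenceMatrix(
        tm_a.network.name, tm_b.network.name, tm_a.order, tm_b.order, c,
        tm_a.index, tm_b.index,
    )


def _safe_scale(sums: np.ndarray) -> np.ndarray:
    inv = np.zeros_like(sums)
    nz = sums > 0
    inv[nz] = 1.0 / sums[nz]
    return inv


def alignment_probabilities(corr: CorrespondenceMatrix) -> ProbMatrix:
    """Average of row- and column-normalised correspondence scores.

    Rows or columns summing to zero contribute zero to their term, so
    unmatched nodes simply get probability 0.
    """
    c = corr.mat
    if c.nnz == 0:
        raise ValueError("empty correspondence matrix")
    row_inv = _safe_scale(np.asarray(c.sum(axis=1)).ravel())
    col_inv = _safe_scale(np.asarray(c.sum(axis=0)).ravel())
    p = 0.5 * (sp.diags(row_inv) @ c + c @ sp.diags(col_inv))
    return ProbMatrix(
        corr.net_a, corr.net_b, corr.nodes_a, corr.nodes_b, p.tocsr(),
        corr.index_a, corr.index_b, stage="raw",
    )
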