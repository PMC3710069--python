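"""Probabilistic consistency transformations.

Two sharpening steps are applied to the raw pairwise alignment
probabilities before alignment construction:

* the intra-network transform mixes each pair's probability with the
  transition-weighted probabilities of its neighbourhood, exploiting the
  fact that orthologs tend to be conserved as connected complexes;
* the cross-network transform propagates probabilities through every
  other network as an intermediate (two-hop products), weighting each
  intermediate by how homologous it is to both endpoint networks.

Both transforms keep the matrices sparse: a transformed value survives
only where the input probability was already positive or where it ranks
in the top `top_fraction` of transformed values for that network pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .smrw import ProbMatrix, TransitionModel


def _sparsify(candidate: sp.csr_matrix, keep_mask: sp.csr_matrix, top_fraction: float):
    """Keep candidate entries where keep_mask is nonzero or the value is
    within the top `top_fraction` quantile of all positive candidate
    values (closed threshold: ties at the cutoff are kept)."""
    cand = candidate.tocoo()
    pos = cand.data > 0
    if not pos.any():
        return sp.csr_matrix(candidate.shape)
    if top_fraction >= 1.0:
        thresh = -np.inf
    else:
        vals = cand.data[pos]
        k = max(1, int(np.ceil(top_fraction * vals.size)))
        thresh = np.partition(vals, vals.size - k)[vals.size - k]
    keep_b = sp.csr_matrix(
        (np.ones(keep_mask.nnz, dtype=np.int8), keep_mask.nonzero()),
        shape=candidate.shape,
    )
    in_support = np.asarray(keep_b[cand.row, cand.col]).ravel() > 0
    sel = pos & ((cand.data >= thresh) | in_support)
    return sp.csr_matrix(
        (cand.data[sel], (cand.row[sel], cand.col[sel])), shape=candidate.shape
    )


def intra_transform(
    p: ProbMatrix,
    tm_a: TransitionModel,
    tm_b: TransitionModel,
    alpha: float = 0.9,
    top_fraction: float = 0.01,
) -> ProbMatrix:
    """Intra-network probabilistic consistency transformation.

    q(x, y) = alpha p(x, y)
            + (1 - alpha) sum_{x' in N(x)} sum_{y' in N(y)}
                          trans_a(x -> x') trans_b(y -> y') p(x', y'),

    i.e. in matrix form  Q = alpha P + (1 - alpha) T_a P T_b'.
    Nodes isolated in their network have an empty neighbour sum, so
    q = alpha p there.
    """
    if p.stage != "raw":
        raise ValueError(f"intra_transform expects a raw matrix, got {p.stage!r}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    q = alpha * p.mat + (1.0 - alpha) * (tm_a.trans @ p.mat @ tm_b.trans.T)
    q = _sparsify(q.tocsr(), p.mat, top_fraction)
    return ProbMatrix(
        p.net_a, p.net_b, p.nodes_a, p.nodes_b, q, p.index_a, p.index_b,
        stage="intra",
    )


@dataclass
class HomologyWeight:
    """Estimated probability that two networks are homologous.

    The value is the total weight of the maximum-weight bipartite
    matching of the alignment-probability matrix, normalised so that two
    identical networks with perfect probabilities score exactly 1.
    """

    net_a: str
    net_b: str
    value: float
    matching: set[tuple[str, str]]


def max_weight_matching(p: ProbMatrix) -> tuple[float, set[tuple[str, str]]]:
    """Exact maximum-weight bipartite matching of the sparse support.

    Solved as a rectangular assignment problem on the dense submatrix
    restricted to nodes that carry at least one positive entry; with
    non-negative weights the optimal assignment value equals the optimal
    partial-matching value, and zero-weight assignments are discarded.
    """
    coo = p.mat.tocoo()
    if coo.nnz == 0:
        return 0.0, set()
    rows = np.unique(coo.row)
    cols = np.unique(coo.col)
    rpos = {r: i for i, r in enumerate(rows)}
    cpos = {c: i for i, c in enumerate(cols)}
    dense = np.zeros((rows.size, cols.size))
    for i, j, v in zip(coo.row, coo.col, coo.data):
        dense[rpos[i], cpos[j]] = max(dense[rpos[i], cpos[j]], v)
    ri, ci = linear_sum_assignment(dense, maximize=True)
    matching = set()
    total = 0.0
    for i, j in zip(ri, ci):
        v = dense[i, j]
        if v > 0:
            matching.add((p.nodes_a[rows[i]], p.nodes_b[cols[j]]))
            total += v
    return total, matching


def homology_weight(p: ProbMatrix, normalizer: str = "min_size") -> HomologyWeight:
    """Network-pair homology probability from the matching of p.

    value = (matching weight) / min(|V_a|, |V_b|), clamped to [0, 1]
    (``normalizer="matching_size"`` divides by the matching cardinality
    instead).
    """
    total, matching = max_weight_matching(p)
    if normalizer == "min_size":
        denom = min(len(p.nodes_a), len(p.nodes_b))
    elif normalizer == "matching_size":
        denom = len(matching)
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    value = total / denom if denom else 0.0
    return HomologyWeight(p.net_a, p.net_b, float(np.clip(value, 0.0, 1.0)), matching)


def cross_transform(
    all_p: dict[frozenset, ProbMatrix],
    weights: dict[frozenset, float],
    net_a: str,
    net_b: str,
    top_fraction: float = 0.01,
) -> ProbMatrix:
    """Cross-network probabilistic consistency transformation.

    With z ranging over every network in the run (a and b included via
    identity matrices and weight 1), r_z = weight(a, z) weight(z, b):

        out = sum_z r_z (P_az P_zb) / sum_z r_z.

    The normalisation by sum_z r_z keeps the output a convex mixture of
    probability matrices, hence in [0, 1], for any weight configuration.
    With exactly two networks in the run the transform is the identity.
    """
    direct = _oriented(all_p, net_a, net_b)
    names = set()
    for key in all_p:
        names |= set(key)
    names |= {net_a, net_b}
    acc = sp.csr_matrix(direct.mat.shape)
    total_r = 0.0
    for z in sorted(names):
        r = _pair_weight(weights, net_a, z) * _pair_weight(weights, z, net_b)
        if r == 0.0:
            continue
        if z == net_a:
            hop = direct.mat
        elif z == net_b:
            hop = direct.mat
        else:
            hop = _oriented(all_p, net_a, z).mat @ _oriented(all_p, z, net_b).mat
        acc = acc + r * hop
        total_r += r
    if total_r == 0.0:
        raise ValueError(f"all intermediate weights vanish for pair ({net_a!r}, {net_b!r})")
    out = _sparsify((acc / total_r).tocsr(), direct.mat, top_fraction)
    return ProbMatrix(
        direct.net_a, direct.net_b, direct.nodes_a, direct.nodes_b, out,
        direct.index_a, direct.index_b, stage="cross",
    )


def _pair_weight(weights: dict[frozenset, float], u: str, v: str) -> float:
    if u == v:
        return 1.0
    key = frozenset((u, v))
    if key not in weights:
        raise KeyError(f"missing homology weight for pair ({u!r}, {v!r})")
    return weights[key]


def _oriented(all_p: dict[frozenset, ProbMatrix], u: str, v: str) -> ProbMatrix:
    key = frozenset((u, v))
    if key not in all_p:
        raise KeyError(f"missing probability matrix for pair ({u!r}, {v!r})")
    p = all_p[key]
    if p.net_a == u and p.net_b == v:
        return p
    return p.transposed()
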