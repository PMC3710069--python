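"""Intra-/cross-network consistency transforms and homology weights."""

import itertools

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from mnalign import (
    Network,
    SimilarityScores,
    alignment_probabilities,
    build_transition_model,
    correspondence_scores,
    cross_transform,
    homology_weight,
    intra_transform,
)
from mnalign.smrw import ProbMatrix

from conftest import (
    brute_force_max_matching,
    random_similarity,
    random_walkable_network,
)


def make_prob(net_a, net_b, nodes_a, nodes_b, dense, stage="raw"):
    return ProbMatrix(
        net_a, net_b, list(nodes_a), list(nodes_b),
        sp.csr_matrix(np.asarray(dense, dtype=float)), stage=stage,
    )


def intra_oracle(p: ProbMatrix, net_a: Network, net_b: Network, alpha: float):
    """Explicit quadruple loop over all neighbour pairs."""
    tm_a = build_transition_model(net_a)
    tm_b = build_transition_model(net_b)
    out = {}
    for x in p.nodes_a:
        for y in p.nodes_b:
            acc = 0.0
            for xp in net_a.graph.neighbors(x):
                for yp in net_b.graph.neighbors(y):
                    acc += (
                        tm_a.trans[tm_a.index[x], tm_a.index[xp]]
                        * tm_b.trans[tm_b.index[y], tm_b.index[yp]]
                        * p.get(xp, yp)
                    )
            out[(x, y)] = alpha * p.get(x, y) + (1 - alpha) * acc
    return out


class TestIntraTransform:
    def test_alpha_one_is_identity(self, rng):
        net_a = random_walkable_network(rng, 5, name="A")
        net_b = random_walkable_network(rng, 5, name="B")
        sim = random_similarity(rng, net_a, net_b)
        tm_a, tm_b = build_transition_model(net_a), build_transition_model(net_b)
        p = alignment_probabilities(correspondence_scores(tm_a, tm_b, sim))
        q = intra_transform(p, tm_a, tm_b, alpha=1.0, top_fraction=0.01)
        assert np.abs(q.mat.toarray() - p.mat.toarray()).max() == 0.0
        assert q.stage == "intra"

    def test_path_graph_hand_value(self, path_pair):
        net_a, net_b = path_pair
        p = make_prob("A", "B", net_a.nodes, net_b.nodes,
                      np.diag([0.9, 0.9, 0.9]))
        tm_a, tm_b = build_transition_model(net_a), build_transition_model(net_b)
        q = intra_transform(p, tm_a, tm_b, alpha=0.9, top_fraction=1.0)
        # 0.9*0.9 + 0.1*(0.5*0.5*0.9 + 0.5*0.5*0.9) = 0.855
        assert q.get("b", "e") == pytest.approx(0.855, abs=1e-12)

    def test_isolated_node_keeps_alpha_fraction(self):
        net_a = Network.from_edges("A", [("a", "b")], nodes=["a", "b", "z"])
        net_b = Network.from_edges("B", [("d", "e")])
        p = make_prob("A", "B", net_a.nodes, net_b.nodes,
                      [[0.5, 0.1], [0.0, 0.6], [0.8, 0.0]])
        tm_a, tm_b = build_transition_model(net_a), build_transition_model(net_b)
        q = intra_transform(p, tm_a, tm_b, alpha=0.7, top_fraction=1.0)
        assert q.get("z", "d") == pytest.approx(0.7 * 0.8)

    def test_matches_quadruple_loop_oracle(self, rng):
        for _ in range(5):
            net_a = random_walkable_network(rng, 6, name="A")
            net_b = random_walkable_network(rng, 5, name="B")
            sim = random_similarity(rng, net_a, net_b)
            tm_a = build_transition_model(net_a)
            tm_b = build_transition_model(net_b)
            p = alignment_probabilities(correspondence_scores(tm_a, tm_b, sim))
            q = intra_transform(p, tm_a, tm_b, alpha=0.9, top_fraction=1.0)
            oracle = intra_oracle(p, net_a, net_b, alpha=0.9)
            for key, val in oracle.items():
                assert q.get(*key) == pytest.approx(val, abs=1e-12)

    def test_entries_stay_in_unit_interval_and_symmetric(self, rng):
        net_a = random_walkable_network(rng, 6, name="A")
        net_b = random_walkable_network(rng, 6, name="B")
        sim = random_similarity(rng, net_a, net_b)
        tm_a, tm_b = build_transition_model(net_a), build_transition_model(net_b)
        p = alignment_probabilities(correspondence_scores(tm_a, tm_b, sim))
        q = intra_transform(p, tm_a, tm_b, alpha=0.9, top_fraction=0.01)
        pt = alignment_probabilities(
            correspondence_scores(tm_b, tm_a, sim.transposed())
        )
        qt = intra_transform(pt, tm_b, tm_a, alpha=0.9, top_fraction=0.01)
        arr = q.mat.toarray()
        assert arr.min() >= 0.0 and arr.max() <= 1.0 + 1e-12
        assert np.abs(arr - qt.mat.toarray().T).max() < 1e-12

    def test_sparsity_filter_keeps_support_and_top_quantile(self):
        net_a = Network.from_edges("A", [(f"a{i}", f"a{i+1}") for i in range(10)])
        net_b = Network.from_edges("B", [(f"b{i}", f"b{i+1}") for i in range(10)])
        dense = np.zeros((11, 11))
        dense[0, 0] = 0.9
        p = make_prob("A", "B", net_a.nodes, net_b.nodes, dense)
        tm_a, tm_b = build_transition_model(net_a), build_transition_model(net_b)
        q = intra_transform(p, tm_a, tm_b, alpha=0.5, top_fraction=0.01)
        # original support always survives
        assert q.get("a0", "b0") > 0
        # neighbour spill-over (a1,b1) must pass the top-quantile gate:
        # with few candidates the closed threshold keeps the max only
        spill = q.mat.toarray()
        assert spill.max() == spill[0, 0]


class TestHomologyWeight:
    def test_identity_networks_perfect_probabilities(self):
        p = make_prob("A", "B", ["x1", "x2"], ["y1", "y2"], np.eye(2),
                      stage="intra")
        hw = homology_weight(p)
        assert hw.value == pytest.approx(1.0)
        assert hw.matching == {("x1", "y1"), ("x2", "y2")}

    def test_all_zero_gives_zero(self):
        p = make_prob("A", "B", ["x1"], ["y1"], [[0.0]], stage="intra")
        hw = homology_weight(p)
        assert hw.value == 0.0 and hw.matching == set()

    def test_hand_2x2_crossing_matching(self):
        p = make_prob("A", "B", ["x1", "x2"], ["y1", "y2"],
                      [[0.8, 0.6], [0.7, 0.1]], stage="intra")
        hw = homology_weight(p)
        assert hw.value == pytest.approx(1.3 / 2)
        assert hw.matching == {("x1", "y2"), ("x2", "y1")}

    @pytest.mark.parametrize("size", [2, 3])
    def test_exhaustive_oracle_all_small_cases(self, rng, size):
        for _ in range(30):
            dense = rng.random((size, size)) * (rng.random((size, size)) < 0.7)
            nodes_a = [f"x{i}" for i in range(size)]
            nodes_b = [f"y{j}" for j in range(size)]
            p = make_prob("A", "B", nodes_a, nodes_b, dense, stage="intra")
            weights = {
                (nodes_a[i], nodes_b[j]): dense[i, j]
                for i in range(size) for j in range(size) if dense[i, j] > 0
            }
            expected = brute_force_max_matching(weights) / size if weights else 0.0
            assert homology_weight(p).value == pytest.approx(
                min(expected, 1.0), abs=1e-12
            )

    def test_agrees_with_networkx_blossom(self, rng):
        """Independent cross-check against general max-weight matching."""
        dense = rng.random((6, 7)) * (rng.random((6, 7)) < 0.4)
        nodes_a = [f"x{i}" for i in range(6)]
        nodes_b = [f"y{j}" for j in range(7)]
        p = make_prob("A", "B", nodes_a, nodes_b, dense, stage="intra")
        g = nx.Graph()
        for i in range(6):
            for j in range(7):
                if dense[i, j] > 0:
                    g.add_edge(("a", i), ("b", j), weight=dense[i, j])
        total = sum(g.edges[e]["weight"] for e in nx.max_weight_matching(g))
        assert homology_weight(p).value == pytest.approx(total / 6, abs=1e-12)

    def test_matching_size_normalizer(self):
        p = make_prob("A", "B", ["x1", "x2", "x3"], ["y1", "y2", "y3"],
                      np.diag([0.5, 0.5, 0.0]), stage="intra")
        assert homology_weight(p, "matching_size").value == pytest.approx(0.5)
        assert homology_weight(p, "min_size").value == pytest.approx(1.0 / 3)


def cross_oracle(mats, weights, names, a, b):
    """Direct triple-loop evaluation of the weighted two-hop mixture."""
    nodes = {n: mats[(n, n)][1] for n in names}
    out = {}

    def w(u, v):  # weight(a, a) = 1 by convention
        return 1.0 if u == v else weights[frozenset((u, v))]

    for x in nodes[a]:
        for y in nodes[b]:
            num = 0.0
            denom = 0.0
            for z in names:
                r = w(a, z) * w(z, b)
                denom += r
                hop = 0.0
                for t in nodes[z]:
                    hop += get(mats, a, z, x, t) * get(mats, z, b, t, y)
                num += r * hop
            out[(x, y)] = num / denom
    return out


def get(mats, u, v, x, y):
    if u == v:
        return 1.0 if x == y else 0.0
    if (u, v) in mats:
        dense, rows, cols = mats[(u, v)][0], mats[(u, v)][1], mats[(u, v)][2]
        return dense[rows.index(x), cols.index(y)]
    dense, rows, cols = mats[(v, u)][0], mats[(v, u)][1], mats[(v, u)][2]
    return dense[rows.index(y), cols.index(x)]


class TestCrossTransform:
    def _pairs(self, mats):
        return {
            frozenset((u, v)): make_prob(u, v, rows, cols, dense, stage="intra")
            for (u, v), (dense, rows, cols) in mats.items() if u != v
        }

    def test_two_network_run_is_identity(self, rng):
        dense = rng.random((3, 4))
        rows = [f"x{i}" for i in range(3)]
        cols = [f"y{j}" for j in range(4)]
        mats = {("A", "B"): (dense, rows, cols)}
        out = cross_transform(self._pairs(mats), {frozenset(("A", "B")): 0.6},
                              "A", "B", top_fraction=1.0)
        assert np.abs(out.mat.toarray() - dense).max() < 1e-12
        assert out.stage == "cross"

    def test_perfect_copy_intermediate_is_idempotent(self, rng):
        dense = rng.random((3, 3))
        xa = [f"x{i}" for i in range(3)]
        yb = [f"y{j}" for j in range(3)]
        zc = [f"z{j}" for j in range(3)]
        mats = {
            ("A", "B"): (dense, xa, yb),
            ("A", "C"): (dense.copy(), xa, zc),
            ("C", "B"): (np.eye(3), zc, yb),
        }
        weights = {frozenset(p): 1.0
                   for p in [("A", "B"), ("A", "C"), ("C", "B")]}
        out = cross_transform(self._pairs(mats), weights, "A", "B",
                              top_fraction=1.0)
        assert np.abs(out.mat.toarray() - dense).max() < 1e-12

    def test_matches_triple_sum_oracle(self, rng):
        for _ in range(5):
            sizes = {"A": 4, "B": 3, "C": 5}
            nodes = {n: [f"{n.lower()}{i}" for i in range(k)]
                     for n, k in sizes.items()}
            mats = {}
            for u, v in [("A", "B"), ("A", "C"), ("B", "C")]:
                mats[(u, v)] = (
                    rng.random((sizes[u], sizes[v]))
                    * (rng.random((sizes[u], sizes[v])) < 0.7),
                    nodes[u], nodes[v],
                )
            weights = {
                frozenset(p): float(rng.uniform(0.1, 1.0))
                for p in [("A", "B"), ("A", "C"), ("B", "C")]
            }
            out = cross_transform(self._pairs(mats), weights, "A", "B",
                                  top_fraction=1.0)
            names = ["A", "B", "C"]
            mats_o = dict(mats)
            for n in names:
                mats_o[(n, n)] = (np.eye(sizes[n]), nodes[n], nodes[n])
            oracle = cross_oracle(mats_o, weights, names, "A", "B")
            for (x, y), val in oracle.items():
                assert out.get(x, y) == pytest.approx(val, abs=1e-12)

    def test_symmetry_and_unit_interval(self, rng):
        sizes = {"A": 4, "B": 4, "C": 4}
        nodes = {n: [f"{n.lower()}{i}" for i in range(4)] for n in sizes}
        mats = {}
        for u, v in [("A", "B"), ("A", "C"), ("B", "C")]:
            mats[(u, v)] = (rng.random((4, 4)), nodes[u], nodes[v])
        weights = {frozenset(p): 0.5
                   for p in [("A", "B"), ("A", "C"), ("B", "C")]}
        pairs = self._pairs(mats)
        out_ab = cross_transform(pairs, weights, "A", "B", top_fraction=1.0)
        out_ba = cross_transform(pairs, weights, "B", "A", top_fraction=1.0)
        arr = out_ab.mat.toarray()
        assert arr.min() >= 0.0 and arr.max() <= 1.0 + 1e-12
        assert np.abs(arr - out_ba.mat.toarray().T).max() < 1e-12

    def test_missing_pair_matrix_named_in_error(self, rng):
        dense = rng.random((2, 2))
        mats = {("A", "B"): (dense, ["x0", "x1"], ["y0", "y1"])}
        pairs = self._pairs(mats)
        weights = {frozenset(("A", "B")): 1.0,
                   frozenset(("A", "C")): 1.0, frozenset(("B", "C")): 1.0}
        pairs_with_c = dict(pairs)
        pairs_with_c[frozenset(("A", "C"))] = make_prob(
            "A", "C", ["x0", "x1"], ["z0"], [[0.5], [0.5]], stage="intra"
        )
        with pytest.raises(KeyError, match="C"):
            cross_transform(pairs_with_c, weights, "A", "B", top_fraction=1.0)

    def test_support_only_shrinks_as_top_fraction_vanishes(self, rng):
        sizes = {"A": 5, "B": 5, "C": 5}
        nodes = {n: [f"{n.lower()}{i}" for i in range(5)] for n in sizes}
        mats = {}
        for u, v in [("A", "B"), ("A", "C"), ("B", "C")]:
            mats[(u, v)] = (
                rng.random((5, 5)) * (rng.random((5, 5)) < 0.3),
                nodes[u], nodes[v],
            )
        weights = {frozenset(p): 1.0
                   for p in [("A", "B"), ("A", "C"), ("B", "C")]}
        pairs = self._pairs(mats)
        small = cross_transform(pairs, weights, "A", "B", top_fraction=0.01)
        big = cross_transform(pairs, weights, "A", "B", top_fraction=0.5)
        support_small = set(zip(*small.mat.nonzero()))
        support_big = set(zip(*big.mat.nonzero()))
        assert support_small <= support_big
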