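"""Subgraph induction techniques and the intuitiveness/exhaustiveness/sparsity metrics."""

import numpy as np
import pytest

import eigsearch as eg
from eigsearch.errors import (
    EmptyExplanationError,
    GraphInvariantError,
    SizeGuardError,
    UnknownTechniqueError,
)
from eigsearch.graph import connected_graphs_up_to


class TestGraphInvariants:
    def test_rejects_self_loop(self):
        with pytest.raises(GraphInvariantError):
            eg.Graph(X=np.ones((2, 1)), edges=[(0, 0, 1.0)])

    def test_rejects_duplicate_and_out_of_range(self):
        with pytest.raises(GraphInvariantError):
            eg.Graph(X=np.ones((3, 1)), edges=[(0, 1, 1.0), (1, 0, 1.0)])
        with pytest.raises(GraphInvariantError):
            eg.Graph(X=np.ones((2, 1)), edges=[(0, 5, 1.0)])
        with pytest.raises(GraphInvariantError):
            eg.Graph(X=np.ones((2, 1)), edges=[(0, 1, 1.5)])

    def test_canonical_order_and_directed_entries(self):
        g = eg.Graph(X=np.ones((3, 1)), edges=[(2, 0, 0.5)])
        assert g.edges == [(0, 2, 0.5)]
        assert g.directed_entries(0) == ((0, 2), (2, 0))
        A = g.adjacency()
        assert A[0, 2] == A[2, 0] == 0.5 and A.sum() == 1.0


class TestInduceSubgraph:
    def test_node_induction_on_triangle(self, k3):
        s = eg.induce_subgraph(k3, "node", VS={0, 1})
        assert s.node_ids == {0, 1} and s.edge_ids == {0}

    def test_edge_induction_recovers_angle_shape(self, k3):
        # the 2-edge path that node induction cannot express on K3
        s = eg.induce_subgraph(k3, "edge", ES={0, 1})
        assert s.node_ids == {0, 1, 2} and s.edge_ids == {0, 1}
        assert eg.induce_subgraph(k3, "node", VS=s.node_ids).edge_ids == {0, 1, 2}

    def test_node_induction_can_leave_isolated_nodes(self, path3):
        s = eg.induce_subgraph(path3, "node", VS={0, 2})
        assert s.node_ids == {0, 2} and s.edge_ids == set()

    def test_node_and_edge_union(self, path3):
        s = eg.induce_subgraph(path3, "node_and_edge", VS={0, 1}, ES={1})
        assert s.node_ids == {0, 1, 2} and s.edge_ids == {0, 1}

    def test_errors(self, k3):
        with pytest.raises(UnknownTechniqueError):
            eg.induce_subgraph(k3, "magic", VS={0})
        with pytest.raises(GraphInvariantError):
            eg.induce_subgraph(k3, "edge", ES={99})

    def test_idempotent_on_own_edges(self):
        for seed in range(20):
            g = eg.random_graph(7, 0.4, seed=seed)
            rng = np.random.default_rng(seed)
            es = set(
                int(e)
                for e in rng.choice(g.num_edges, size=max(1, g.num_edges // 2), replace=False)
            )
            s1 = eg.induce_subgraph(g, "edge", ES=es)
            s2 = eg.induce_subgraph(g, "edge", ES=s1.edge_ids)
            assert s1.node_ids == s2.node_ids and s1.edge_ids == s2.edge_ids


class TestIntuitiveness:
    def test_edge_induced_path(self, k3):
        assert eg.intuitiveness(eg.induce_subgraph(k3, "edge", ES={0, 1})) == 1.0

    def test_isolated_pair(self, path3):
        assert eg.intuitiveness(eg.induce_subgraph(path3, "node", VS={0, 2})) == 0.0

    def test_mixed_components(self):
        g = eg.Graph(X=np.ones((4, 1)), edges=[(0, 1, 1.0), (2, 3, 1.0)])
        s = eg.induce_subgraph(g, "node_and_edge", VS={2}, ES={0})
        assert eg.intuitiveness(s) == 0.5  # one edge component + isolated node

    def test_empty_explanation_raises(self, k3):
        with pytest.raises(EmptyExplanationError):
            eg.intuitiveness(eg.induce_subgraph(k3, "edge", ES=set()))

    def test_edge_induced_always_one_and_dominates_node(self):
        """Edge induction never creates isolated nodes; node induction can."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = eg.random_graph(
                int(rng.integers(4, 10)), 0.4, seed=int(rng.integers(2**31 - 1))
            )
            vs = set(
                int(v)
                for v in rng.choice(g.n, size=int(rng.integers(1, g.n)), replace=False)
            )
            node_s = eg.induce_subgraph(g, "node", VS=vs)
            if node_s.edge_ids:
                edge_s = eg.induce_subgraph(g, "edge", ES=node_s.edge_ids)
                assert eg.intuitiveness(edge_s) == 1.0
                assert eg.intuitiveness(edge_s) >= eg.intuitiveness(node_s)
            es = set(
                int(e)
                for e in rng.choice(g.num_edges, size=min(3, g.num_edges), replace=False)
            )
            assert eg.intuitiveness(eg.induce_subgraph(g, "edge", ES=es)) == 1.0


class TestExhaustiveness:
    def test_triangle_values(self, k3):
        # 7 connected >=1-edge subgraphs: 3 edges, 3 two-edge paths, triangle
        assert eg.exhaustiveness("edge", k3) == 1.0
        assert eg.exhaustiveness("node", k3) == pytest.approx(4 / 7)
        assert eg.exhaustiveness("node_and_edge", k3) == 1.0

    def test_single_edge_graph(self):
        g = eg.Graph(X=np.ones((2, 1)), edges=[(0, 1, 1.0)])
        for t in ("node", "edge", "node_and_edge"):
            assert eg.exhaustiveness(t, g) == 1.0

    def test_size_guard(self):
        g = eg.random_graph(14, 0.9, seed=0)
        with pytest.raises(SizeGuardError):
            eg.exhaustiveness("edge", g)

    def test_edge_dominates_node_on_all_small_connected_graphs(self):
        """Over every connected graph up to 5 nodes, by full enumeration."""
        for g in connected_graphs_up_to(5):
            x_edge = eg.exhaustiveness("edge", g)
            x_node = eg.exhaustiveness("node", g)
            assert x_edge >= x_node
            assert x_edge == eg.exhaustiveness("node_and_edge", g)


class TestSparsity:
    def test_formula(self):
        g = eg.random_graph(8, 0.5, seed=1)
        assert g.num_edges >= 3
        es = set(range(3))
        s = eg.induce_subgraph(g, "edge", ES=es)
        assert eg.sparsity(s, g) == pytest.approx(1 - 3 / g.num_edges)

    def test_identity_and_empty(self, k3):
        full = eg.induce_subgraph(k3, "edge", ES={0, 1, 2})
        assert eg.sparsity(full, k3) == 0.0
        empty = eg.induce_subgraph(k3, "edge", ES=set())
        assert eg.sparsity(empty, k3) == 1.0

    def test_node_unit(self, k3):
        s = eg.induce_subgraph(k3, "node", VS={0, 1})
        assert eg.sparsity(s, k3, unit="nodes") == pytest.approx(1 / 3)
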