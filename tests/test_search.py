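"""Ranking, the linear prefix search, oracles and baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eigsearch as eg
from eigsearch.errors import GraphInvariantError, SizeGuardError
from conftest import graph_with_edges


def probe_for(g: eg.Graph) -> eg.FunctionPredictor:
    return eg.edge_count_probe(denominator=2.0 * g.num_edges)


class TestRankEdges:
    def test_descending_with_id_ties(self):
        s = eg.EdgeScores(target_class=1, scores=[0.1, 0.9, 0.5], method="linear_grad")
        assert eg.rank_edges(s).tolist() == [1, 2, 0]

    def test_all_equal_gives_identity(self):
        s = eg.EdgeScores(target_class=1, scores=[0.3, 0.3, 0.3], method="linear_grad")
        assert eg.rank_edges(s).tolist() == [0, 1, 2]

    def test_invariant_to_positive_scaling(self):
        rng = np.random.default_rng(0)
        sc = rng.normal(size=12)
        a = eg.rank_edges(eg.EdgeScores(1, sc, "linear_grad"))
        b = eg.rank_edges(eg.EdgeScores(1, 7.3 * sc, "linear_grad"))
        assert a.tolist() == b.tolist()

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_is_a_stable_permutation(self, scores):
        order = eg.rank_edges(eg.EdgeScores(0, scores, "linear_grad"))
        assert sorted(order.tolist()) == list(range(len(scores)))
        ranked = [scores[i] for i in order]
        assert ranked == sorted(scores, reverse=True)
        for a, b in zip(order, order[1:]):  # equal scores keep id order
            if scores[a] == scores[b]:
                assert a < b


class TestLinearSearch:
    def test_triangle_probe(self, k3, probe):
        res = eg.linear_search(probe, k3, np.array([0, 1, 2]))
        assert res.best_k == 2
        assert res.best_score == pytest.approx(0.25)
        assert [k for k, _ in res.candidates] == [2]  # range 2..|E|-1 on |E|=3

    def test_candidate_count(self):
        g = graph_with_edges(10, seed=1)
        res = eg.linear_search(probe_for(g), g, np.arange(10))
        assert len(res.candidates) == 8

    def test_constant_predictor_ties_to_smallest_k(self):
        g = graph_with_edges(6, seed=2)
        res = eg.linear_search(eg.constant_probe([0.5, 0.5]), g, np.arange(6))
        assert res.best_k == 2 and res.best_score == 0.0

    def test_best_equals_max_over_candidates(self, k3, probe):
        g = graph_with_edges(9, seed=3)
        p = probe_for(g)
        res = eg.linear_search(p, g, np.arange(9), k_range="full")
        assert res.best_score == max(rep.overall for _, rep in res.candidates)
        first_best = min(
            k for k, rep in res.candidates if rep.overall == res.best_score
        )
        assert res.best_k == first_best

    def test_requires_permutation(self, k3, probe):
        with pytest.raises(GraphInvariantError):
            eg.linear_search(probe, k3, np.array([0, 0, 1]))


class TestExplainGraph:
    def test_forward_call_audit(self):
        g = graph_with_edges(10, seed=4)
        _, res, _ = eg.explain_graph(probe_for(g), g)
        assert res.forward_calls == 1 + 10 + 2 * 8

    def test_linear_complexity_slope(self):
        sizes = [10, 20, 40, 80]
        calls = []
        for m in sizes:
            g = graph_with_edges(m, seed=m)
            _, res, _ = eg.explain_graph(probe_for(g), g)
            assert res.forward_calls == 1 + m + 2 * (m - 2)
            calls.append(res.forward_calls)
        slope = np.polyfit(sizes, calls, 1)[0]
        assert slope == pytest.approx(3.0, abs=0.01)

    def test_explanation_is_edge_induced_with_unit_intuitiveness(self):
        g = graph_with_edges(12, seed=5)
        expl, _, _ = eg.explain_graph(probe_for(g), g)
        assert expl.technique == "edge"
        assert eg.intuitiveness(expl) == 1.0

    def test_rerun_identical(self):
        g = graph_with_edges(8, seed=6)
        p = probe_for(g)
        _, r1, s1 = eg.explain_graph(p, g)
        _, r2, s2 = eg.explain_graph(p, g)
        assert r1.best_k == r2.best_k and r1.best_score == r2.best_score
        np.testing.assert_array_equal(s1.scores, s2.scores)
        np.testing.assert_array_equal(r1.ranked_edges, r2.ranked_edges)


class TestBruteForce:
    def test_triangle_optimum(self, k3, probe):
        es, score = eg.brute_force_best_subset(probe, k3)
        assert len(es) == 2 and score == pytest.approx(0.25)

    def test_single_edge_graph(self):
        g = eg.Graph(X=np.ones((2, 1)), edges=[(0, 1, 1.0)])
        es, _ = eg.brute_force_best_subset(eg.edge_count_probe(2.0), g)
        assert es == {0}

    def test_size_guard(self):
        g = graph_with_edges(11, seed=7)
        with pytest.raises(SizeGuardError):
            eg.brute_force_best_subset(probe_for(g), g, max_edges=8)

    def test_oracle_dominates_linear_search(self):
        """The pruned search never beats exhaustive enumeration; it matches
        it whenever the optimum happens to be a ranking prefix."""
        rng = np.random.default_rng(10)
        checked = 0
        for seed in range(200):
            g = eg.random_graph(5, 0.5, seed=seed)
            # |E| >= 3 keeps the default search range inside the oracle's
            # proper-subset candidate space
            if not (3 <= g.num_edges <= 8):
                continue
            beta = rng.normal(scale=0.02, size=(5, 5))
            np.fill_diagonal(beta, 0.0)
            p = eg.affine_edge_probe((beta + beta.T) / 2)
            _, res, _ = eg.explain_graph(p, g)
            _, oracle = eg.brute_force_best_subset(p, g)
            assert oracle >= res.best_score - 1e-12
            checked += 1
            if checked >= 60:
                break
        assert checked >= 50


class TestFixedSize:
    def test_sparsity_to_k(self):
        g = graph_with_edges(10, seed=8)
        expl = eg.fixed_size_explanation(g, np.arange(10), sparsity=0.7)
        assert expl.chosen_k == 3 and expl.sparsity == pytest.approx(0.7)

    def test_full_size(self):
        g = graph_with_edges(5, seed=9)
        expl = eg.fixed_size_explanation(g, np.arange(5), k=5)
        assert expl.num_edges == 5 and expl.sparsity == 0.0

    def test_minimum_one_edge(self):
        g = graph_with_edges(10, seed=10)
        expl = eg.fixed_size_explanation(g, np.arange(10), sparsity=0.99)
        assert expl.chosen_k == 1

    def test_target_validation(self):
        g = graph_with_edges(4, seed=11)
        with pytest.raises(ValueError):
            eg.fixed_size_explanation(g, np.arange(4))
        with pytest.raises(GraphInvariantError):
            eg.fixed_size_explanation(g, np.arange(4), k=9)
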