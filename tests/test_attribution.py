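"""Linear-gradient scoring and the saliency / integrated-gradients baselines."""

import numpy as np
import pytest

import eigsearch as eg
from eigsearch.errors import CapabilityError, ZeroDistanceError


def random_affine_probe(n, seed, scale=0.02):
    rng = np.random.default_rng(seed)
    beta = rng.normal(scale=scale, size=(n, n))
    np.fill_diagonal(beta, 0.0)
    return eg.affine_edge_probe(beta), beta


class TestBaseAdjacency:
    def test_empty_target_is_identity(self, k3):
        np.testing.assert_array_equal(eg.base_adjacency(k3, []), k3.adjacency())

    def test_all_edges_to_zero(self, k3):
        assert not eg.base_adjacency(k3, range(3)).any()

    def test_single_edge_zeroed_both_directions(self, k3):
        A = eg.base_adjacency(k3, [0])
        assert A[0, 1] == A[1, 0] == 0.0
        assert A.sum() == 4.0  # the other two edges keep both entries


class TestLinearGradient:
    def test_single_edge_on_probe(self, k3, probe):
        # (0.75 - 0.50) / 2 directed entries
        assert eg.linear_gradient(probe, k3, [0], c=1) == pytest.approx(0.125)

    def test_whole_edge_set_on_probe(self, k3, probe):
        # (0.75 - 0.0) / 6 directed entries
        assert eg.linear_gradient(probe, k3, [0, 1, 2], c=1) == pytest.approx(0.125)

    def test_constant_predictor_scores_zero(self, k3):
        p = eg.constant_probe([0.4, 0.6])
        assert eg.linear_gradient(p, k3, [0], c=1) == 0.0

    def test_zero_distance_raises(self, k3, probe):
        with pytest.raises(ZeroDistanceError):
            eg.linear_gradient(probe, k3, [], c=1)
        g = eg.Graph(X=np.ones((2, 1)), edges=[(0, 1, 0.0)])
        with pytest.raises(ZeroDistanceError):
            eg.linear_gradient(probe, g, [0], c=1)

    def test_distance_scales_with_weights(self):
        """Halving all weights halves |A - A^t|; the slope is recomputed fresh."""
        full = eg.Graph(X=np.ones((3, 1)), edges=[(0, 1, 1.0), (1, 2, 1.0)])
        half = eg.Graph(X=np.ones((3, 1)), edges=[(0, 1, 0.5), (1, 2, 0.5)])
        d_full = np.abs(full.adjacency() - eg.base_adjacency(full, [0])).sum()
        d_half = np.abs(half.adjacency() - eg.base_adjacency(half, [0])).sum()
        assert d_half == d_full / 2
        p, beta = random_affine_probe(3, seed=5)
        # affine slope is weight-independent: numerator scales with the distance
        assert eg.linear_gradient(p, full, [0], c=1) == pytest.approx(
            eg.linear_gradient(p, half, [0], c=1)
        )


class TestScoreEdges:
    def test_forward_call_budget(self, probe):
        g = eg.random_graph(7, 0.5, seed=11)
        counter = eg.CountingPredictor(eg.edge_count_probe(denominator=50.0))
        eg.score_edges(counter, g, method="linear_grad")
        assert counter.forward_calls == g.num_edges + 1

    @pytest.mark.parametrize("steps", [1, 7, 100])
    def test_ig_equals_linear_grad_for_affine(self, steps):
        g = eg.random_graph(5, 0.7, seed=2)
        p, beta = random_affine_probe(5, seed=3)
        lg = eg.score_edges(p, g, c=1, method="linear_grad").scores
        ig = eg.score_edges(p, g, c=1, method="ig", ig_steps=steps).scores
        np.testing.assert_allclose(ig, lg, atol=1e-8)

    def test_sa_matches_affine_coefficients(self):
        g = eg.random_graph(5, 0.7, seed=4)
        p, beta = random_affine_probe(5, seed=9)
        sa = eg.score_edges(p, g, c=1, method="sa").scores
        expect = [abs(beta[u, v]) + abs(beta[v, u]) for u, v, _ in g.edges]
        np.testing.assert_allclose(sa, expect, atol=1e-12)

    def test_saturation_separates_methods(self, two_edge_graph):
        """Local gradients vanish in the sigmoid's flat region; the
        baseline-anchored slope still sees the dominant edge."""
        p = eg.saturating_probe((0, 1), (2, 3))
        sa = eg.score_edges(p, two_edge_graph, c=1, method="sa").scores
        lg = eg.score_edges(p, two_edge_graph, c=1, method="linear_grad").scores
        assert sa.max() < 1e-4
        assert lg[0] > 10 * abs(lg[1]) and lg[0] > 0.1

    def test_sa_requires_gradient_capability(self, k3):
        p = eg.FunctionPredictor(lambda A, X: np.array([0.5, 0.5]))
        with pytest.raises(CapabilityError):
            eg.score_edges(p, k3, c=1, method="sa")

    def test_deterministic(self, k3, probe):
        s1 = eg.score_edges(probe, k3, method="linear_grad").scores
        s2 = eg.score_edges(probe, k3, method="linear_grad").scores
        np.testing.assert_array_equal(s1, s2)

    def test_default_class_is_prediction(self, k3, probe):
        assert eg.score_edges(probe, k3).target_class == 1


class TestNodeSaliency:
    def test_constant_predictor_all_zero(self, k3):
        assert not eg.node_saliency(eg.constant_probe([0.5, 0.5]), k3).any()

    def test_symmetric_predictor_equal_scores(self, k3):
        def fn(A, X):
            p1 = float(np.clip(X[:, 0].mean(), 0, 1))
            return np.array([1 - p1, p1])

        def feat_grad(A, X, c):
            g = np.zeros_like(X)
            g[:, 0] = 1.0 / X.shape[0]
            return g if c == 1 else -g

        p = eg.FunctionPredictor(fn, 2, feature_grad_fn=feat_grad)
        s = eg.node_saliency(p, k3, c=1)
        assert np.allclose(s, s[0]) and (s >= 0).all()
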