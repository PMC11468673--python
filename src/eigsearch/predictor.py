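"""The predictor contract and small closed-form probe predictors.

Everything downstream (attribution, fidelity, search) talks to a model only
through :class:`Predictor`: a deterministic map from a weighted adjacency
``A`` and node features ``X`` to a probability vector over classes.  Edge
weights live in [0, 1] and a weight of 0 means the edge is absent — that
convention is what makes occlusion (setting an edge's two directed entries
to a base weight of 0) equivalent to deleting the edge.

Gradient access (with respect to adjacency entries or node features) is an
optional capability: the linear-gradient scorer needs none, while the
vanilla-saliency and integrated-gradients baselines do.  Probe predictors
used in tests carry analytic gradients; the reference GNN differentiates
numerically.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .errors import CapabilityError, ContractError
from .graph import Graph

_SIMPLEX_ATOL = 1e-6


class Predictor:
    """Deterministic graph classifier: ``(A, X) -> probability vector``.

    Subclasses implement :meth:`_forward`; :func:`predict_proba` is the
    validated public entry point.
    """

    num_classes: int = 2
    supports_edge_gradients: bool = False
    supports_feature_gradients: bool = False

    def _forward(self, A: np.ndarray, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def edge_gradients(self, A: np.ndarray, X: np.ndarray, c: int) -> np.ndarray:
        """d p(c) / d A_uv as an n x n matrix."""
        raise CapabilityError(f"{type(self).__name__} does not expose edge gradients")

    def feature_gradients(self, A: np.ndarray, X: np.ndarray, c: int) -> np.ndarray:
        """d p(c) / d X as an n x d matrix."""
        raise CapabilityError(f"{type(self).__name__} does not expose feature gradients")


def predict_proba(p: Predictor, A: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Evaluate a predictor and enforce the output contract."""
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ContractError(f"adjacency must be square, got shape {A.shape}")
    if X.ndim != 2 or X.shape[0] != A.shape[0]:
        raise ContractError(
            f"features {X.shape} incompatible with adjacency {A.shape}"
        )
    if not (np.isfinite(A).all() and np.isfinite(X).all()):
        raise ContractError("non-finite entries in predictor input")
    out = np.asarray(p._forward(A, X), dtype=float)
    if out.shape != (p.num_classes,):
        raise ContractError(
            f"predictor returned shape {out.shape}, expected ({p.num_classes},)"
        )
    if not np.isfinite(out).all() or (out < -_SIMPLEX_ATOL).any():
        raise ContractError("predictor output not a valid probability vector")
    if abs(out.sum() - 1.0) > _SIMPLEX_ATOL:
        raise ContractError(f"predictor output sums to {out.sum()}, not 1")
    return out


def edge_gradients(p: Predictor, A: np.ndarray, X: np.ndarray, c: int) -> np.ndarray:
    if not p.supports_edge_gradients:
        raise CapabilityError(
            f"{type(p).__name__} does not support edge gradients; "
            "the linear-gradient scorer needs no gradients at all"
        )
    g = np.asarray(p.edge_gradients(np.asarray(A, float), np.asarray(X, float), int(c)))
    if g.shape != A.shape or not np.isfinite(g).all():
        raise ContractError("edge gradient has wrong shape or non-finite entries")
    return g


def feature_gradients(p: Predictor, A: np.ndarray, X: np.ndarray, c: int) -> np.ndarray:
    if not p.supports_feature_gradients:
        raise CapabilityError(f"{type(p).__name__} does not support feature gradients")
    g = np.asarray(p.feature_gradients(np.asarray(A, float), np.asarray(X, float), int(c)))
    if g.shape != X.shape or not np.isfinite(g).all():
        raise ContractError("feature gradient has wrong shape or non-finite entries")
    return g


class CountingPredictor(Predictor):
    """Wrapper that counts forward evaluations (for complexity audits)."""

    def __init__(self, inner: Predictor):
        self.inner = inner
        self.num_classes = inner.num_classes
        self.supports_edge_gradients = inner.supports_edge_gradients
        self.supports_feature_gradients = inner.supports_feature_gradients
        self.forward_calls = 0

    def _forward(self, A: np.ndarray, X: np.ndarray) -> np.ndarray:
        self.forward_calls += 1
        return self.inner._forward(A, X)

    def edge_gradients(self, A, X, c):
        return self.inner.edge_gradients(A, X, c)

    def feature_gradients(self, A, X, c):
        return self.inner.feature_gradients(A, X, c)

    def reset(self) -> None:
        self.forward_calls = 0


class FunctionPredictor(Predictor):
    """Predictor built from a closure ``fn(A, X) -> probs``.

    Optional analytic gradient closures turn on the corresponding
    capabilities.  Used for the probe predictors below and in tests.
    """

    def __init__(
        self,
        fn: Callable[[np.ndarray, np.ndarray], np.ndarray],
        num_classes: int = 2,
        edge_grad_fn: Optional[Callable[[np.ndarray, np.ndarray, int], np.ndarray]] = None,
        feature_grad_fn: Optional[Callable[[np.ndarray, np.ndarray, int], np.ndarray]] = None,
    ):
        self.fn = fn
        self.num_classes = num_classes
        self._edge_grad_fn = edge_grad_fn
        self._feature_grad_fn = feature_grad_fn
        self.supports_edge_gradients = edge_grad_fn is not None
        self.supports_feature_gradients = feature_grad_fn is not None

    def _forward(self, A, X):
        return self.fn(A, X)

    def edge_gradients(self, A, X, c):
        if self._edge_grad_fn is None:
            return super().edge_gradients(A, X, c)
        return self._edge_grad_fn(A, X, c)

    def feature_gradients(self, A, X, c):
        if self._feature_grad_fn is None:
            return super().feature_gradients(A, X, c)
        return self._feature_grad_fn(A, X, c)


# -- probe predictors (closed-form oracles) --------------------------------


def edge_count_probe(denominator: float = 4.0) -> FunctionPredictor:
    """p(class 1) = (total undirected edge weight) / denominator.

    On an unweighted triangle with the default denominator this gives
    (0.25, 0.75): three edges out of four "units".  Affine in every
    adjacency entry, so all attribution methods agree on it exactly.
    """

    def fn(A, X):
        p1 = A.sum() / (2.0 * denominator)
        return np.array([1.0 - p1, p1])

    def edge_grad(A, X, c):
        g = np.full_like(A, 1.0 / (2.0 * denominator))
        np.fill_diagonal(g, 0.0)
        return g if c == 1 else -g

    def feat_grad(A, X, c):
        return np.zeros_like(X)

    return FunctionPredictor(fn, 2, edge_grad_fn=edge_grad, feature_grad_fn=feat_grad)


def affine_edge_probe(coefficients: np.ndarray, intercept: float = 0.5) -> FunctionPredictor:
    """p(class 1) = clip-free affine function of adjacency entries.

    ``coefficients`` is an n x n matrix of per-directed-entry slopes; the
    caller is responsible for keeping outputs within [0, 1] on the inputs
    it evaluates.
    """
    coefficients = np.asarray(coefficients, dtype=float)

    def fn(A, X):
        p1 = intercept + float((coefficients * A).sum())
        return np.array([1.0 - p1, p1])

    def edge_grad(A, X, c):
        return coefficients.copy() if c == 1 else -coefficients

    return FunctionPredictor(fn, 2, edge_grad_fn=edge_grad)


def saturating_probe(
    edge_a: tuple[int, int],
    edge_b: tuple[int, int],
    coef_a: float = 5.0,
    coef_b: float = 0.1,
    gain: float = 10.0,
    shift: float = 40.0,
) -> FunctionPredictor:
    """A deeply saturated two-edge classifier.

    p(class 1) = sigmoid(gain * (coef_a * s_a + coef_b * s_b) - shift), where
    ``s_e`` sums the two directed adjacency entries of edge ``e``.  At unit
    weights the operand sits far into the sigmoid's flat region, so local
    (vanilla) gradients vanish at the data point even though occluding edge
    ``a`` collapses the prediction — the classic saturation failure mode of
    point-gradient saliency that slope-to-baseline scores do not share.
    """
    (ua, va), (ub, vb) = edge_a, edge_b

    def _z(A):
        s_a = A[ua, va] + A[va, ua]
        s_b = A[ub, vb] + A[vb, ub]
        return gain * (coef_a * s_a + coef_b * s_b) - shift

    def fn(A, X):
        p1 = 1.0 / (1.0 + np.exp(-_z(A)))
        return np.array([1.0 - p1, p1])

    def edge_grad(A, X, c):
        p1 = 1.0 / (1.0 + np.exp(-_z(A)))
        d = p1 * (1.0 - p1)
        g = np.zeros_like(A)
        g[ua, va] = g[va, ua] = gain * coef_a * d
        g[ub, vb] = g[vb, ub] = gain * coef_b * d
        return g if c == 1 else -g

    return FunctionPredictor(fn, 2, edge_grad_fn=edge_grad)


def constant_probe(probs: np.ndarray) -> FunctionPredictor:
    """Predictor ignoring its input entirely (zero gradients everywhere)."""
    probs = np.asarray(probs, dtype=float)

    def fn(A, X):
        return probs.copy()

    return FunctionPredictor(
        fn,
        len(probs),
        edge_grad_fn=lambda A, X, c: np.zeros_like(A),
        feature_grad_fn=lambda A, X, c: np.zeros_like(X),
    )


def predict_graph(p: Predictor, G: Graph) -> np.ndarray:
    """Convenience: evaluate a predictor on a Graph's own adjacency/features."""
    return predict_proba(p, G.adjacency(), G.X)
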