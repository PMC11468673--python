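"""Edge attribution: linear gradients plus saliency / integrated-gradients baselines.

The linear-gradient score of an edge set ``Et`` for class ``c`` is the slope
of the straight line, in output space, between the model's prediction at
the original adjacency ``A`` and at the baseline adjacency ``A^t`` in which
the edges of ``Et`` are set to their base weight (0 by default — complete
absence of signal)::

    s(c | Et) = (p(c | A, X) - p(c | A^t, X)) / |A - A^t|

where ``|.|`` is the entrywise L1 distance over directed adjacency entries
(2 * w for a single undirected edge of weight w with base 0).  Being a
secant slope rather than a point derivative, the score is immune to
saturation: a flat local gradient cannot hide an edge whose removal moves
the prediction.  It needs only forward evaluations — one per edge plus one
for the intact graph — so it applies to any black-box predictor.

Per-edge scoring sets ``Et`` to the edge's two directed entries.  Scores
keep their sign: a negative score marks counter-evidence for the target
class.

The baselines are the standard gradient attributions transplanted to edge
weights: vanilla saliency (absolute local gradient, sign discarded) and
integrated gradients along the straight path from the all-base adjacency.
The IG edge score is normalized by the edge's own L1 baseline distance,
making it an average slope directly comparable to the linear gradient (for
a predictor affine in edge weights the two coincide for any step count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

import numpy as np

from .errors import GraphInvariantError, ZeroDistanceError
from .graph import Graph
from .predictor import (
    Predictor,
    edge_gradients,
    feature_gradients,
    predict_proba,
)

ScoreMethod = Literal["linear_grad", "sa", "ig"]


@dataclass
class BaseAssignment:
    """Baseline edge weights: a scalar default plus optional per-edge overrides."""

    base_weight: float = 0.0
    per_edge: Optional[dict[int, float]] = None

    def weight_for(self, edge_id: int) -> float:
        if self.per_edge and edge_id in self.per_edge:
            w = self.per_edge[edge_id]
        else:
            w = self.base_weight
        if not (0.0 <= w <= 1.0):
            raise GraphInvariantError(f"base weight {w} outside [0,1]")
        return w


@dataclass
class EdgeScores:
    """Per-undirected-edge importance for one target class."""

    target_class: int
    scores: np.ndarray
    method: ScoreMethod
    ig_steps: Optional[int] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise GraphInvariantError("edge scores must be finite")


def base_adjacency(
    G: Graph, Et: Iterable[int], base: Optional[BaseAssignment] = None
) -> np.ndarray:
    """Adjacency with the edges of Et moved to their base weights.

    Both directed entries of each targeted edge are set; untouched edges
    keep their weight and non-edges stay 0.
    """
    base = base or BaseAssignment()
    A = G.adjacency()
    for e in Et:
        e = int(e)
        if not (0 <= e < G.num_edges):
            raise GraphInvariantError(f"edge id {e} not in the graph")
        (u, v), (v2, u2) = G.directed_entries(e)
        w = base.weight_for(e)
        A[u, v] = w
        A[v, u] = w
    return A


def linear_gradient(
    p: Predictor,
    G: Graph,
    Et: Iterable[int],
    c: Optional[int] = None,
    base: Optional[BaseAssignment] = None,
    p_full: Optional[np.ndarray] = None,
) -> float:
    """Slope of the line from the base point of Et to the data point."""
    Et = list(Et)
    A = G.adjacency()
    At = base_adjacency(G, Et, base)
    dist = float(np.abs(A - At).sum())
    if dist == 0.0:
        raise ZeroDistanceError(
            "baseline equals the input adjacency (empty Et or weights already at base)"
        )
    if p_full is None:
        p_full = predict_proba(p, A, G.X)
    if c is None:
        c = int(np.argmax(p_full))
    p_base = predict_proba(p, At, G.X)
    return float((p_full[c] - p_base[c]) / dist)


def score_edges(
    p: Predictor,
    G: Graph,
    c: Optional[int] = None,
    method: ScoreMethod = "linear_grad",
    base: Optional[BaseAssignment] = None,
    ig_steps: int = 32,
    p_full: Optional[np.ndarray] = None,
) -> EdgeScores:
    """Score every explainable edge of G for class c (default: predicted class).

    linear_grad needs |E| + 1 forward passes in total (one of which is the
    shared prediction on the intact graph, reused if ``p_full`` is given).
    sa / ig require the predictor's edge-gradient capability.
    """
    if G.num_edges == 0:
        raise GraphInvariantError("graph has no explainable edges to score")
    base = base or BaseAssignment()
    A = G.adjacency()
    if p_full is None:
        p_full = predict_proba(p, A, G.X)
    if c is None:
        c = int(np.argmax(p_full))

    scores = np.empty(G.num_edges)
    if method == "linear_grad":
        for e in range(G.num_edges):
            scores[e] = linear_gradient(p, G, [e], c=c, base=base, p_full=p_full)
    elif method == "sa":
        g = edge_gradients(p, A, G.X, c)
        for e in range(G.num_edges):
            (u, v), (v2, u2) = G.directed_entries(e)
            scores[e] = abs(g[u, v]) + abs(g[v, u])
    elif method == "ig":
        if ig_steps < 1:
            raise ValueError("ig requires at least one step")
        A_base = base_adjacency(G, range(G.num_edges), base)
        delta = A - A_base
        g_sum = np.zeros_like(A)
        for k in range(ig_steps):
            alpha = (k + 0.5) / ig_steps  # midpoint rule
            g_sum += edge_gradients(p, A_base + alpha * delta, G.X, c)
        mean_g = g_sum / ig_steps
        for e in range(G.num_edges):
            (u, v), _ = G.directed_entries(e)
            d = abs(delta[u, v]) + abs(delta[v, u])
            if d == 0.0:
                raise ZeroDistanceError(
                    f"edge {e} already at its base weight; IG slope undefined"
                )
            scores[e] = (delta[u, v] * mean_g[u, v] + delta[v, u] * mean_g[v, u]) / d
    else:
        raise ValueError(f"unknown scoring method {method!r}")

    return EdgeScores(
        target_class=c,
        scores=scores,
        method=method,
        ig_steps=ig_steps if method == "ig" else None,
    )


def node_saliency(p: Predictor, G: Graph, c: Optional[int] = None) -> np.ndarray:
    """Per-node L2 norm of the feature gradient (node-level baseline)."""
    A = G.adjacency()
    if c is None:
        c = int(np.argmax(predict_proba(p, A, G.X)))
    g = feature_gradients(p, A, G.X, c)
    return np.linalg.norm(g, axis=1)
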