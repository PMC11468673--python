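"""Subgraph-level fidelity metrics.

For an explanation edge set ``ES`` of graph ``G`` with predicted class
``y`` (the class the model assigns to the intact graph):

* ``Fidelity+`` — drop in p(y) when the explanation is removed, i.e. when
  only the complement edge set E \\ ES is kept.  High means the explanation
  was necessary.
* ``Fidelity-`` — drop in p(y) when only the explanation is kept.  Low
  means the explanation is sufficient.
* ``overall = Fidelity+ - Fidelity-`` — the single objective the search
  maximizes when choosing the explanation size.

Both terms are computed on the *edge-induced* subgraph of the kept edge
set, never by deleting nodes (deleting a node would strand its incident
edges).  Two evaluation policies are offered:

* ``mask`` (default): all n nodes are kept and removed edges get weight 0.
  This matches the base-weight-0 convention of the attribution module and
  never produces a degenerate empty graph.
* ``induce``: strict edge induction — nodes not incident to a kept edge
  are dropped before evaluation.  For models whose pooling ignores
  isolated nodes the two agree; they are both reported because the choice
  is a genuine semantic knob.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np

from .errors import GraphInvariantError
from .graph import Graph
from .predictor import Predictor, predict_proba

FidelityPolicy = Literal["mask", "induce"]


@dataclass
class FidelityReport:
    y: int
    fid_plus: float
    fid_minus: float
    policy: FidelityPolicy

    @property
    def overall(self) -> float:
        return self.fid_plus - self.fid_minus


def evaluate_edge_set(
    p: Predictor, G: Graph, edge_ids: Iterable[int], policy: FidelityPolicy = "mask"
) -> np.ndarray:
    """Model output when exactly ``edge_ids`` are kept.

    mask: zero out every other edge's two directed entries, keep all nodes.
    induce: evaluate the edge-induced subgraph on its own nodes (an empty
    edge set degenerates to the masked all-zero adjacency, since a model
    needs at least one node to evaluate).
    """
    kept = set(int(e) for e in edge_ids)
    if not kept <= set(range(G.num_edges)):
        raise GraphInvariantError("edge_ids not a subset of the graph's edges")

    if policy == "mask" or not kept:
        A = np.zeros((G.n, G.n))
        for e in kept:
            u, v, w = G.edges[e]
            A[u, v] = w
            A[v, u] = w
        return predict_proba(p, A, G.X)
    if policy == "induce":
        nodes = sorted({x for e in kept for x in G.endpoints(e)})
        relabel = {v: i for i, v in enumerate(nodes)}
        A = np.zeros((len(nodes), len(nodes)))
        for e in kept:
            u, v, w = G.edges[e]
            A[relabel[u], relabel[v]] = w
            A[relabel[v], relabel[u]] = w
        return predict_proba(p, A, G.X[nodes])
    raise ValueError(f"unknown fidelity policy {policy!r}")


def fidelity_report(
    p: Predictor,
    G: Graph,
    ES: Iterable[int],
    policy: FidelityPolicy = "mask",
    y: Optional[int] = None,
    p_full: Optional[np.ndarray] = None,
) -> FidelityReport:
    """Fidelity+/- of the explanation edge set ES.

    ``y``/``p_full`` may be passed in so the intact-graph prediction is
    computed once per graph and shared across all candidate explanations.
    """
    if G.num_edges == 0:
        raise GraphInvariantError("fidelity undefined on an edgeless graph")
    es = set(int(e) for e in ES)
    if not es <= set(range(G.num_edges)):
        raise GraphInvariantError("ES is not a subset of the graph's edges")
    if p_full is None:
        p_full = predict_proba(p, G.adjacency(), G.X)
    if y is None:
        y = int(np.argmax(p_full))

    complement = set(range(G.num_edges)) - es
    p_without = evaluate_edge_set(p, G, complement, policy)
    p_only = evaluate_edge_set(p, G, es, policy)
    return FidelityReport(
        y=y,
        fid_plus=float(p_full[y] - p_without[y]),
        fid_minus=float(p_full[y] - p_only[y]),
        policy=policy,
    )
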