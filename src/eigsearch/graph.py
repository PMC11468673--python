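"""Graph container and subgraph-inducing techniques.

A :class:`Graph` stores an undirected, optionally edge-weighted graph for
graph classification: a node-feature matrix ``X`` (n x d) and a canonical
undirected edge list (``u < v``, weight in [0, 1]).  Each undirected edge
corresponds to the two directed adjacency entries ``(u, v)`` and ``(v, u)``;
:meth:`Graph.directed_entries` exposes that mapping, which the attribution
and fidelity code relies on when it perturbs the adjacency.

Self-loops are not part of the explainable edge set: message-passing layers
typically add their own, so a loop carries no subgraph-level meaning here.

The module also implements the three ways a subgraph-level explanation can
be induced from a selection — by nodes, by edges, or by both — together with
the metrics used to compare them:

* ``intuitiveness``: the fraction of an explanation's connected components
  that contain at least one edge (isolated nodes are unintuitive as
  "subgraph" explanations);
* ``exhaustiveness``: the fraction of all connected >=1-edge subgraphs of a
  graph that a technique can express at all, by brute-force enumeration;
* ``sparsity``: 1 - |S|/|G|, the fraction of the graph left out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import (
    EmptyExplanationError,
    GraphInvariantError,
    SizeGuardError,
    UnknownTechniqueError,
)

Technique = Literal["node", "edge", "node_and_edge"]
TECHNIQUES = ("node", "edge", "node_and_edge")

#: Enumeration guard for `exhaustiveness`: subsets of nodes and of edges are
#: both iterated, so each count is capped.
ENUMERATION_GUARD = 12


@dataclass(eq=False)
class Graph:
    """Undirected weighted graph with node features and an optional label."""

    X: np.ndarray
    edges: list[tuple[int, int, float]]
    label: Optional[int] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise GraphInvariantError("X must be a 2-d (n x d) matrix")
        n = self.X.shape[0]
        canon: list[tuple[int, int, float]] = []
        seen: set[tuple[int, int]] = set()
        for e in self.edges:
            u, v, w = int(e[0]), int(e[1]), float(e[2])
            if u == v:
                raise GraphInvariantError(f"self-loop ({u},{v}) is not explainable")
            if not (0 <= u < n and 0 <= v < n):
                raise GraphInvariantError(f"edge ({u},{v}) endpoint out of range [0,{n})")
            if u > v:
                u, v = v, u
            if (u, v) in seen:
                raise GraphInvariantError(f"duplicate undirected edge ({u},{v})")
            if not (0.0 <= w <= 1.0) or not np.isfinite(w):
                raise GraphInvariantError(f"edge ({u},{v}) weight {w} outside [0,1]")
            seen.add((u, v))
            canon.append((u, v, w))
        self.edges = canon

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric weighted adjacency (both directed entries per edge)."""
        A = np.zeros((self.n, self.n))
        for u, v, w in self.edges:
            A[u, v] = w
            A[v, u] = w
        return A

    def directed_entries(self, edge_id: int) -> tuple[tuple[int, int], tuple[int, int]]:
        """The two directed adjacency entries of one undirected edge."""
        u, v, _ = self.edges[edge_id]
        return (u, v), (v, u)

    def endpoints(self, edge_id: int) -> tuple[int, int]:
        u, v, _ = self.edges[edge_id]
        return u, v

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        for i, (u, v, w) in enumerate(self.edges):
            g.add_edge(u, v, weight=w, edge_id=i)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return (
            self.n == other.n
            and self.label == other.label
            and self.edges == other.edges
            and np.array_equal(self.X, other.X)
        )


@dataclass
class SubgraphExplanation:
    """A technique-tagged induced subgraph of a parent graph.

    ``edge_ids`` index into ``parent.edges``; ``sparsity`` is measured in
    edges (the unit the search optimizes over).
    """

    parent: Graph
    technique: Technique
    node_ids: frozenset[int]
    edge_ids: frozenset[int]
    fidelity: Optional["object"] = None  # FidelityReport, set by the search
    chosen_k: Optional[int] = None
    sparsity: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not self.node_ids <= set(range(self.parent.n)):
            raise GraphInvariantError("explanation nodes outside parent graph")
        if not self.edge_ids <= set(range(self.parent.num_edges)):
            raise GraphInvariantError("explanation edges outside parent graph")
        for e in self.edge_ids:
            u, v = self.parent.endpoints(e)
            if u not in self.node_ids or v not in self.node_ids:
                raise GraphInvariantError(
                    f"retained edge {e} has an endpoint outside the retained nodes"
                )

    @property
    def num_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def num_edges(self) -> int:
        return len(self.edge_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.node_ids))
        for e in sorted(self.edge_ids):
            u, v, w = self.parent.edges[e]
            g.add_edge(u, v, weight=w, edge_id=e)
        return g


@dataclass
class ComponentDecomposition:
    """Connected components of an explanation, split by whether they carry edges."""

    components: list[tuple[frozenset[int], frozenset[int]]]

    @property
    def C(self) -> int:
        """Total number of connected components (isolated nodes included)."""
        return len(self.components)

    @property
    def C_S(self) -> int:
        """Components with at least one node and at least one edge."""
        return sum(1 for nodes, edges in self.components if nodes and edges)


def decompose(S: SubgraphExplanation) -> ComponentDecomposition:
    g = S.to_networkx()
    comps = []
    for nodes in nx.connected_components(g):
        edge_ids = frozenset(
            data["edge_id"] for _, _, data in g.subgraph(nodes).edges(data=True)
        )
        comps.append((frozenset(nodes), edge_ids))
    return ComponentDecomposition(components=comps)


def induce_subgraph(
    G: Graph,
    technique: Technique,
    VS: Optional[Iterable[int]] = None,
    ES: Optional[Iterable[int]] = None,
) -> SubgraphExplanation:
    """Induce a subgraph-level explanation from a node and/or edge selection.

    * ``node``: keep the nodes ``VS`` and every edge with both endpoints kept.
    * ``edge``: keep the edges ``ES`` and exactly their endpoints (never
      leaves an isolated node).
    * ``node_and_edge``: nodes = ``VS`` plus endpoints of ``ES``; edges =
      ``ES`` plus all edges internal to ``VS``.
    """
    if technique not in TECHNIQUES:
        raise UnknownTechniqueError(f"unknown technique {technique!r}")
    vs = frozenset(int(v) for v in VS) if VS is not None else frozenset()
    es = frozenset(int(e) for e in ES) if ES is not None else frozenset()
    if not vs <= set(range(G.n)):
        raise GraphInvariantError("VS contains node ids outside the graph")
    if not es <= set(range(G.num_edges)):
        raise GraphInvariantError("ES contains edge ids outside the graph")

    if technique == "node":
        nodes = vs
        edges = frozenset(
            i for i, (u, v, _) in enumerate(G.edges) if u in vs and v in vs
        )
    elif technique == "edge":
        edges = es
        nodes = frozenset(v for e in es for v in G.endpoints(e))
    else:
        internal = frozenset(
            i for i, (u, v, _) in enumerate(G.edges) if u in vs and v in vs
        )
        edges = es | internal
        nodes = vs | frozenset(v for e in es for v in G.endpoints(e))

    spars = 1.0 - (len(edges) / G.num_edges) if G.num_edges else 0.0
    return SubgraphExplanation(
        parent=G, technique=technique, node_ids=nodes, edge_ids=edges, sparsity=spars
    )


def intuitiveness(S: SubgraphExplanation) -> float:
    """Fraction of the explanation's components that contain an edge (C_S / C)."""
    if not S.node_ids:
        raise EmptyExplanationError("intuitiveness is undefined on an empty explanation")
    dec = decompose(S)
    return dec.C_S / dec.C


def sparsity(
    S: SubgraphExplanation, G: Graph, unit: Literal["edges", "nodes"] = "edges"
) -> float:
    """1 - |S|/|G| in the chosen unit (edges by default)."""
    if unit == "edges":
        total, kept = G.num_edges, S.num_edges
    elif unit == "nodes":
        total, kept = G.n, S.num_nodes
    else:
        raise ValueError(f"unknown sparsity unit {unit!r}")
    if total == 0:
        raise GraphInvariantError(f"graph has zero size in unit {unit!r}")
    return 1.0 - kept / total


# -- exhaustiveness by brute-force enumeration -----------------------------
#
# A connected subgraph with >=1 edge is determined by its edge set (its node
# set is exactly the endpoints: any further node would be isolated and the
# subgraph disconnected).  Enumerating connected edge subsets therefore
# enumerates all candidate "subgraph components" of Definition-style
# exhaustiveness exactly once.


def _connected_edge_subsets(G: Graph) -> set[frozenset[int]]:
    out: set[frozenset[int]] = set()
    ids = range(G.num_edges)
    for r in range(1, G.num_edges + 1):
        for subset in combinations(ids, r):
            nodes: dict[int, int] = {}
            parent: list[int] = []

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for e in subset:
                for v in G.endpoints(e):
                    if v not in nodes:
                        nodes[v] = len(parent)
                        parent.append(len(parent))
            for e in subset:
                u, v = (nodes[x] for x in G.endpoints(e))
                ru, rv = find(u), find(v)
                if ru != rv:
                    parent[ru] = rv
            if len({find(i) for i in range(len(parent))}) == 1:
                out.add(frozenset(subset))
    return out


def exhaustiveness(technique: Technique, G: Graph) -> float:
    """Fraction of G's connected >=1-edge subgraphs expressible by a technique.

    Brute-force enumeration; guarded to small graphs
    (n <= 12 and |E| <= 12).
    """
    if technique not in TECHNIQUES:
        raise UnknownTechniqueError(f"unknown technique {technique!r}")
    if G.num_edges > ENUMERATION_GUARD or G.n > ENUMERATION_GUARD:
        raise SizeGuardError(
            f"exhaustiveness enumeration limited to {ENUMERATION_GUARD} nodes/edges"
        )
    if G.num_edges == 0:
        raise GraphInvariantError("exhaustiveness undefined for an edgeless graph")

    all_subgraphs = _connected_edge_subsets(G)

    if technique in ("edge", "node_and_edge"):
        # The edge technique realizes any connected edge subset directly; the
        # node-and-edge technique contains it as the special case VS = empty,
        # and can produce nothing further that is connected with >=1 edge
        # (an extra VS node either attaches through an internal edge, giving
        # another edge subset, or stays isolated and disconnects the result).
        inducible = all_subgraphs
    else:
        inducible = set()
        node_ids = range(G.n)
        for r in range(2, G.n + 1):
            for vs in combinations(node_ids, r):
                vset = set(vs)
                edges = frozenset(
                    i for i, (u, v, _) in enumerate(G.edges) if u in vset and v in vset
                )
                if edges in all_subgraphs:
                    # connected + touches every selected node
                    touched = {x for e in edges for x in G.endpoints(e)}
                    if touched == vset:
                        inducible.add(edges)
    return len(inducible) / len(all_subgraphs)


def connected_graphs_up_to(n_max: int) -> list[Graph]:
    """All connected unlabeled simple graphs with 2..n_max nodes (one per
    isomorphism class is *not* attempted; one per labeled edge set on
    {0..n-1}, deduplicated by isomorphism via networkx)."""
    out: list[Graph] = []
    for n in range(2, n_max + 1):
        seen: list[nx.Graph] = []
        all_pairs = list(combinations(range(n), 2))
        for r in range(n - 1, len(all_pairs) + 1):
            for subset in combinations(all_pairs, r):
                g = nx.Graph()
                g.add_nodes_from(range(n))
                g.add_edges_from(subset)
                if not nx.is_connected(g):
                    continue
                if any(nx.is_isomorphic(g, h) for h in seen):
                    continue
                seen.append(g)
                out.append(
                    Graph(
                        X=np.ones((n, 1)),
                        edges=[(u, v, 1.0) for u, v in sorted(subset)],
                    )
                )
    return out
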