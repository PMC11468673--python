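"""Seeded synthetic motif benchmarks with ground-truth explanation masks.

Two generators, both emitting labeled graphs together with a boolean
per-edge mask marking the edges a faithful explainer should recover:

* :func:`generate_ba2motifs_like` — an emulation of the classic
  house-vs-cycle benchmark: each graph is a Barabasi-Albert base (20
  nodes, attachment 1, i.e. a random tree) with one 5-node motif attached
  by a single edge.  A "house" motif (4-cycle plus a roof triangle, 6
  edges) gives class 0; a 5-cycle (5 edges) gives class 1.  Node features
  are a constant 10-dim vector, so the classes are separable only through
  structure.  The ground-truth mask is exactly the motif's internal edges;
  the attachment edge is excluded.
* :func:`generate_variable_motif` — a molecule-flavored set in which the
  *true explanation size varies between instances*: positives are a
  6-ring skeleton carrying one or two pendant nitro-like groups (a center
  atom with two leaf atoms, distinct one-hot feature codes), negatives
  carry inert carbon pendants instead.  A one-copy positive has 3
  ground-truth edges (attachment + two center-leaf bonds), a two-copy
  positive has 6 — the setting where any fixed explanation size must be
  wrong for part of the dataset.

Both generators are fully determined by their seed.  Classes are balanced
within one graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import networkx as nx
import numpy as np

from .graph import Graph

FEATURE_DIM_BA2 = 10
#: one-hot feature codes for the variable-motif set
ATOM_CODES = {"C": 0, "N": 1, "O": 2}


@dataclass
class SyntheticGraphSet:
    graphs: list[Graph]
    gt_edge_masks: list[np.ndarray]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.graphs)

    def split(self, test_fraction: float = 0.2, seed: Optional[int] = None):
        """Seeded shuffle split; returns (train idx, test idx)."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        order = rng.permutation(len(self.graphs))
        n_test = max(1, int(round(test_fraction * len(self.graphs))))
        return sorted(order[n_test:].tolist()), sorted(order[:n_test].tolist())


_HOUSE_EDGES = [(0, 1), (1, 2), (2, 3), (3, 0), (0, 4), (1, 4)]  # 4-cycle + roof
_CYCLE_EDGES = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)]


def generate_ba2motifs_like(
    n_graphs: int = 300,
    base_nodes: int = 20,
    seed: int = 0,
) -> SyntheticGraphSet:
    """House-motif (class 0) vs cycle-motif (class 1) graphs on BA bases."""
    if n_graphs < 2:
        raise ValueError("need at least two graphs (one per class)")
    if base_nodes < 5:
        raise ValueError("base graph needs at least 5 nodes")
    rng = np.random.default_rng(seed)
    graphs: list[Graph] = []
    masks: list[np.ndarray] = []
    # alternate classes so any prefix is balanced within +-1
    for i in range(n_graphs):
        label = i % 2
        base_seed = int(rng.integers(0, 2**31 - 1))
        base = nx.barabasi_albert_graph(base_nodes, 1, seed=base_seed)
        motif_edges = _CYCLE_EDGES if label == 1 else _HOUSE_EDGES
        offset = base_nodes
        edges = [(u, v, 1.0) for u, v in sorted(base.edges())]
        attach_at = int(rng.integers(0, base_nodes))
        edges.append((attach_at, offset, 1.0))  # attachment edge (not ground truth)
        gt = [False] * len(edges)
        for u, v in motif_edges:
            edges.append((offset + u, offset + v, 1.0))
            gt.append(True)
        n = base_nodes + 5
        X = np.full((n, FEATURE_DIM_BA2), 0.1)
        graphs.append(Graph(X=X, edges=edges, label=label))
        masks.append(np.array(gt))
    return SyntheticGraphSet(
        graphs=graphs,
        gt_edge_masks=masks,
        params={
            "generator": "ba2motifs_like",
            "n_graphs": n_graphs,
            "base_nodes": base_nodes,
        },
        seed=seed,
    )


def _one_hot(code: str, n_rows: int = 1) -> np.ndarray:
    x = np.zeros((n_rows, len(ATOM_CODES)))
    x[:, ATOM_CODES[code]] = 1.0
    return x


def generate_variable_motif(
    n_graphs: int = 200,
    motif_copies: Union[int, Sequence[int]] = (1, 2),
    seed: int = 0,
) -> SyntheticGraphSet:
    """Ring skeletons with 1-2 nitro-like pendant motifs (positives) or inert
    carbon pendants (negatives); ground-truth size varies with the copy count."""
    if n_graphs < 2:
        raise ValueError("need at least two graphs")
    copies = (motif_copies,) if isinstance(motif_copies, int) else tuple(motif_copies)
    if not copies or any(c not in (1, 2) for c in copies):
        raise ValueError("motif copies must be drawn from {1, 2}")
    rng = np.random.default_rng(seed)
    graphs: list[Graph] = []
    masks: list[np.ndarray] = []
    ring = 6
    for i in range(n_graphs):
        label = i % 2
        feats = [_one_hot("C", ring)]
        edges = [(u, (u + 1) % ring, 1.0) for u in range(ring)]
        gt = [False] * ring
        nxt = ring
        if label == 1:
            n_copies = int(rng.choice(copies))
            sites = rng.choice(ring, size=n_copies, replace=False)
            for site in sites:
                center, leaf_a, leaf_b = nxt, nxt + 1, nxt + 2
                nxt += 3
                feats.append(_one_hot("N"))
                feats.append(_one_hot("O", 2))
                edges.append((int(site), center, 1.0))
                edges.append((center, leaf_a, 1.0))
                edges.append((center, leaf_b, 1.0))
                gt.extend([True, True, True])
        else:
            # inert pendants: same size distribution as one motif copy,
            # but plain carbon chains so only the feature codes differ
            n_pend = int(rng.choice(copies))
            sites = rng.choice(ring, size=n_pend, replace=False)
            for site in sites:
                a, b, c_ = nxt, nxt + 1, nxt + 2
                nxt += 3
                feats.append(_one_hot("C", 3))
                edges.append((int(site), a, 1.0))
                edges.append((a, b, 1.0))
                edges.append((a, c_, 1.0))
                gt.extend([False, False, False])
        X = np.vstack(feats)
        graphs.append(Graph(X=X, edges=edges, label=label))
        masks.append(np.array(gt))
    return SyntheticGraphSet(
        graphs=graphs,
        gt_edge_masks=masks,
        params={"generator": "variable_motif", "n_graphs": n_graphs, "copies": copies},
        seed=seed,
    )


def random_graph(
    n: int, p: float, seed: int, feature_dim: int = 4, ensure_edge: bool = True
) -> Graph:
    """Erdos-Renyi test graph with random features and unit edge weights."""
    rng = np.random.default_rng(seed)
    edges = [
        (u, v, 1.0)
        for u in range(n)
        for v in range(u + 1, n)
        if rng.random() < p
    ]
    if ensure_edge and not edges:
        edges = [(0, 1, 1.0)]
    X = rng.random((n, feature_dim))
    return Graph(X=X, edges=edges)
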