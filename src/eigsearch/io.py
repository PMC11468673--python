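"""Serialization: graph documents (JSON), the TUDataset text format, and
explanation reports.

Graph JSON schema (version 1)::

    {"schema_version": 1,
     "graphs": [{"n": int,
                 "x": [[float, ...], ...],          # n rows
                 "edges": [[u, v, w], ...],          # undirected, u < v
                 "label": int | null,
                 "gt_edge_mask": [bool, ...] | null  # optional, per edge
                }, ...]}

Round trips are lossless including edge order.

The TUDataset reader consumes the standard sparse text triple
(``<name>_A.txt``, ``<name>_graph_indicator.txt``,
``<name>_graph_labels.txt``, optional ``<name>_node_labels.txt``): 1-based
global node ids, each undirected edge listed as two directed lines.  The
reader collapses the directed duplicates into canonical undirected edges
(rejecting asymmetric adjacency), converts to 0-based per-graph ids, maps
the label alphabet to 0..K-1, and one-hot encodes node labels into X
(constant single feature when absent).  Formats without weights get unit
edge weight.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .attribution import EdgeScores
from .errors import SchemaError
from .graph import Graph
from .search import SearchResult

SCHEMA_VERSION = 1


# -- graph documents -------------------------------------------------------


def write_graphs(
    graphs: Sequence[Graph],
    path: str | Path,
    gt_edge_masks: Optional[Sequence[np.ndarray]] = None,
) -> None:
    if gt_edge_masks is not None and len(gt_edge_masks) != len(graphs):
        raise SchemaError("one ground-truth mask per graph required")
    docs = []
    for i, G in enumerate(graphs):
        doc = {
            "n": G.n,
            "x": G.X.tolist(),
            "edges": [[u, v, w] for u, v, w in G.edges],
            "label": G.label,
            "gt_edge_mask": None,
        }
        if gt_edge_masks is not None:
            mask = list(map(bool, gt_edge_masks[i]))
            if len(mask) != G.num_edges:
                raise SchemaError(f"mask length mismatch for graph {i}")
            doc["gt_edge_mask"] = mask
        docs.append(doc)
    payload = {"schema_version": SCHEMA_VERSION, "graphs": docs}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_graph_set(path: str | Path) -> tuple[list[Graph], list[Optional[np.ndarray]]]:
    """Read a graph JSON document; returns (graphs, per-graph gt masks or None)."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"expected graph document schema version {SCHEMA_VERSION}, "
            f"got {payload.get('schema_version') if isinstance(payload, dict) else payload!r}"
        )
    graphs, masks = [], []
    for i, doc in enumerate(payload["graphs"]):
        X = np.asarray(doc["x"], dtype=float)
        if X.shape[0] != doc["n"]:
            raise SchemaError(f"graph {i}: feature rows != n")
        label = doc.get("label")
        G = Graph(
            X=X,
            edges=[(int(u), int(v), float(w)) for u, v, w in doc["edges"]],
            label=None if label is None else int(label),
        )
        graphs.append(G)
        mask = doc.get("gt_edge_mask")
        if mask is not None:
            if len(mask) != G.num_edges:
                raise SchemaError(f"graph {i}: mask length mismatch")
            mask = np.asarray(mask, dtype=bool)
        masks.append(mask)
    return graphs, masks


# -- TUDataset sparse text format ------------------------------------------


def _find_prefix(directory: Path) -> str:
    hits = sorted(directory.glob("*_A.txt"))
    if len(hits) != 1:
        raise SchemaError(
            f"expected exactly one *_A.txt under {directory}, found {len(hits)}"
        )
    return hits[0].name[: -len("_A.txt")]


def read_tud(directory: str | Path) -> list[Graph]:
    directory = Path(directory)
    prefix = _find_prefix(directory)

    def lines(suffix: str, required: bool = True) -> Optional[list[str]]:
        f = directory / f"{prefix}_{suffix}.txt"
        if not f.exists():
            if required:
                raise SchemaError(f"missing {f.name}")
            return None
        return [ln.strip() for ln in f.read_text().splitlines() if ln.strip()]

    indicator = [int(x) for x in lines("graph_indicator")]
    raw_labels = [int(float(x)) for x in lines("graph_labels")]
    n_graphs = max(indicator)
    if sorted(set(indicator)) != list(range(1, n_graphs + 1)):
        raise SchemaError("graph indicator ids must cover 1..N")
    if len(raw_labels) != n_graphs:
        raise SchemaError("one graph label per graph required")
    label_map = {l: i for i, l in enumerate(sorted(set(raw_labels)))}

    node_label_lines = lines("node_labels", required=False)
    node_labels = None
    if node_label_lines is not None:
        if len(node_label_lines) != len(indicator):
            raise SchemaError("one node label per node required")
        vals = [int(float(x.split(",")[0])) for x in node_label_lines]
        alphabet = {l: i for i, l in enumerate(sorted(set(vals)))}
        node_labels = [alphabet[v] for v in vals]
        feat_dim = len(alphabet)

    # global (1-based) node id -> (graph, local 0-based id)
    local_of: dict[int, tuple[int, int]] = {}
    counts = [0] * (n_graphs + 1)
    for node, gid in enumerate(indicator, start=1):
        local_of[node] = (gid, counts[gid])
        counts[gid] += 1

    directed: dict[int, dict[tuple[int, int], float]] = {g: {} for g in range(1, n_graphs + 1)}
    for ln in lines("A"):
        parts = ln.replace(",", " ").split()
        if len(parts) not in (2, 3):
            raise SchemaError(f"malformed adjacency line {ln!r}")
        u, v = int(parts[0]), int(parts[1])
        w = float(parts[2]) if len(parts) == 3 else 1.0
        if u not in local_of or v not in local_of:
            raise SchemaError(f"adjacency references unknown node in line {ln!r}")
        (gu, lu), (gv, lv) = local_of[u], local_of[v]
        if gu != gv:
            raise SchemaError(f"edge {u}->{v} crosses graphs {gu} and {gv}")
        if (lu, lv) in directed[gu]:
            raise SchemaError(f"duplicate directed edge {u}->{v}")
        directed[gu][(lu, lv)] = w

    graphs = []
    for gid in range(1, n_graphs + 1):
        entries = directed[gid]
        edges = []
        for (u, v), w in sorted(entries.items()):
            if u == v:
                continue  # self-loops are model-internal, not explainable edges
            if u < v:
                w_back = entries.get((v, u))
                if w_back is None or not math.isclose(w_back, w):
                    raise SchemaError(
                        f"asymmetric adjacency for nodes ({u},{v}) in graph {gid}"
                    )
                edges.append((u, v, w))
        n = counts[gid]
        if node_labels is not None:
            X = np.zeros((n, feat_dim))
            for node, (g, loc) in local_of.items():
                if g == gid:
                    X[loc, node_labels[node - 1]] = 1.0
        else:
            X = np.ones((n, 1))
        graphs.append(Graph(X=X, edges=edges, label=label_map[raw_labels[gid - 1]]))
    return graphs


def read_graphs(path: str | Path, format: str = "json") -> list[Graph]:
    if format == "json":
        return read_graph_set(path)[0]
    if format == "tud":
        return read_tud(path)
    raise SchemaError(f"unknown graph format {format!r}")


# -- explanation documents --------------------------------------------------


def explanation_document(
    graph_id: int | str,
    result: SearchResult,
    scores: EdgeScores,
    policy: str,
    seed: Optional[int] = None,
) -> dict:
    from . import __version__

    doc = {
        "graph_id": graph_id,
        "predicted_class": int(scores.target_class),
        "scorer": scores.method,
        "ranked_edges": [
            {"edge_id": int(e), "score": float(scores.scores[e])}
            for e in result.ranked_edges
        ],
        "candidates": [
            {
                "k": int(k),
                "fid_plus": rep.fid_plus,
                "fid_minus": rep.fid_minus,
                "overall": rep.overall,
            }
            for k, rep in result.candidates
        ],
        "best_k": int(result.best_k),
        "best_overall": float(result.best_score),
        "chosen_edges": sorted(int(e) for e in result.explanation.edge_ids),
        "sparsity": float(result.explanation.sparsity),
        "policy": policy,
        "forward_calls": int(result.forward_calls),
        "seed": seed,
        "tool_version": __version__,
    }
    _validate_finite(doc)
    if doc["chosen_edges"] != sorted(int(e) for e in result.ranked_edges[: result.best_k]):
        raise SchemaError("chosen edges are not the best_k ranking prefix")
    return doc


def _validate_finite(obj, path: str = "") -> None:
    if isinstance(obj, float) and not math.isfinite(obj):
        raise SchemaError(f"non-finite value at {path or 'document root'}")
    if isinstance(obj, dict):
        for k, v in obj.items():
            _validate_finite(v, f"{path}.{k}")
    if isinstance(obj, list):
        for i, v in enumerate(obj):
            _validate_finite(v, f"{path}[{i}]")


def write_explanations(documents: Sequence[dict], path: str | Path) -> None:
    for doc in documents:
        _validate_finite(doc)
    Path(path).write_text(
        json.dumps({"schema_version": SCHEMA_VERSION, "explanations": list(documents)},
                   sort_keys=True)
    )


def read_explanations(path: str | Path) -> list[dict]:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError("unknown explanation document schema version")
    return payload["explanations"]
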