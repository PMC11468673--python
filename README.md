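# eigsearch

Training-free, model-agnostic subgraph explanations for graph classifiers,
with a per-instance explanation size chosen by a linear-time search over
top-k edge-induced subgraphs.

## The problem

Given a trained graph classifier `φ(A, X) → ℝ^C` (a GNN or any black box
over a weighted adjacency `A` and node features `X`) and one input graph —
say a molecule classified as mutagenic — which subgraph is responsible for
the prediction?  Two design choices dominate the quality of such
explanations:

1. **How the subgraph is induced.** Selecting *edges* and keeping exactly
   their endpoints always yields connected, isolated-node-free structures
   and can express every connected subgraph of the input (an angle of a
   triangle, for instance), which node selection cannot.  The package
   implements and measures all three conventions — node-, edge-, and
   node-and-edge-induced — via two metrics: *intuitiveness* (fraction of an
   explanation's components that contain an edge) and *exhaustiveness*
   (fraction of all connected subgraphs a technique can express, by
   brute-force enumeration).
2. **How large the explanation is.** The right size differs between
   instances (one nitro group or two), so any fixed size or fixed sparsity
   must be wrong for part of a dataset.

## The method

**Phase 1 — linear-gradient edge scores.** Each edge `e` is scored by the
slope between the model's output at a baseline adjacency `A^t` (the edge's
two directed entries set to base weight 0, i.e. complete absence) and at
the input:

```
s(c | E_t) = ( φ(c | A, X) − φ(c | A^t, X) ) / |A − A^t|
```

with `|·|` the entrywise L1 distance over directed entries.  As a secant
slope rather than a point derivative, the score does not suffer from
saturation (flat local gradients), and it needs only forward passes — one
per edge.

**Phase 2 — linear search over ranked prefixes.** Edges are sorted by
score; for each k in the search range the top-k edge-induced subgraph `S`
is evaluated by its overall fidelity

```
Fidelity+(S) − Fidelity−(S)
  = [φ(G)_y − φ(G[E∖E_S])_y] − [φ(G)_y − φ(G[E_S])_y]
```

(the prediction drop when the explanation is removed, minus the drop when
only the explanation is kept), and the argmax is returned.  This prunes
the 2^|E| subsets to O(|E|) candidates and two forward passes each —
3|E| + O(1) model evaluations end to end — while selecting a per-instance
explanation size, and by construction the searched explanation never
scores below any fixed-size prefix of the same ranking.

The package also ships: saliency and integrated-gradients edge baselines,
an exhaustive search oracle for small graphs, a NumPy reference GCN/GIN
with a seeded trainer, synthetic motif benchmarks with ground-truth edge
masks (house-vs-cycle on Barabási–Albert bases, and a variable-size
nitro-like motif set), fidelity-vs-sparsity evaluation protocols, a graph
JSON schema plus a TUDataset text-format reader, and a CLI.

## Worked example

```python
import numpy as np
import eigsearch as eg

# a triangle, and a probe classifier p(class 1) = (#edges)/4
K3 = eg.Graph(X=np.ones((3, 2)), edges=[(0, 1, 1.0), (0, 2, 1.0), (1, 2, 1.0)])
probe = eg.edge_count_probe(denominator=4.0)

print(eg.predict_graph(probe, K3))           # [0.25 0.75] -> class 1
print(eg.linear_gradient(probe, K3, [0]))    # 0.125  = (0.75-0.50)/2
rep = eg.fidelity_report(probe, K3, [0])
print(rep.fid_plus, rep.fid_minus, rep.overall)   # 0.25 0.5 -0.25

expl, result, scores = eg.explain_graph(probe, K3)
print(result.best_k, result.best_score)      # 2 0.25
```

Removing one edge costs 0.25 of p(class 1) (`fid_plus`), but that edge
alone also fails to retain the prediction (`fid_minus` 0.5), so a
single-edge explanation has negative overall fidelity; the search instead
selects the two-edge subgraph, whose overall fidelity 0.25 is also the
global optimum over all edge subsets of this graph.

The full pipeline on synthetic data:

```bash
eig-search synth --generator ba2motifs --n-graphs 300 --seed 0 --out graphs.json
eig-search train --graphs graphs.json --seed 0 --out model.npz
eig-search explain --graphs graphs.json --model model.npz --scorer linear_grad --out expl.json
eig-search evaluate --graphs graphs.json --model model.npz --gt --out report.json
```

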