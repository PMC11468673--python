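# Methods notes

This note records the models, conventions, numerical choices and known
limitations behind `eigsearch`, in the order a user meets them.

## Graph model and conventions

A graph is a node-feature matrix `X ∈ ℝ^{n×d}` plus a canonical undirected
edge list `(u, v, w)` with `u < v` and `w ∈ [0, 1]`.  Every undirected edge
owns the two directed adjacency entries `(u, v)` and `(v, u)`; all
perturbations (occlusion, baselines, masking) act on both entries at once.
A weight of 0 is defined to mean "edge absent", and the reference GNNs
enter edge weights multiplicatively on messages so that this holds exactly
(zeroing an edge's entries is bitwise-identical to deleting the edge).
Self-loops are excluded from the explainable edge set — message-passing
layers add their own with fixed weight 1 — and the TUDataset reader drops
them on ingestion.

## Subgraph induction and its metrics

Three induction techniques are implemented: node-induced (keep selected
nodes plus all internal edges), edge-induced (keep selected edges plus
exactly their endpoints), and the node-and-edge union of both.
*Intuitiveness* is `C_S / C`: the fraction of an explanation's connected
components that contain at least one edge; an isolated node counts as a
component with zero edges.  For an empty explanation (no nodes) the ratio
is 0/0 and we raise rather than define it.  *Exhaustiveness* of a
technique on a graph is the fraction of all connected ≥1-edge subgraphs
the technique can express.  It is computed by brute-force enumeration,
using the fact that a connected subgraph with at least one edge is
identified by its edge set (its nodes are exactly the endpoints); the
enumeration is guarded to graphs with at most 12 nodes and 12 edges.  The
node-and-edge count reuses the edge-subset enumeration through the
`VS = ∅` reduction: any extra selected node either attaches through an
internal edge (yielding another edge subset) or stays isolated and
disconnects the result, so no further connected ≥1-edge subgraphs exist.

## The predictor contract

Everything downstream sees a model only as a deterministic map
`(A, X) → probability vector` accepting any edge weights in `[0, 1]`.
Outputs are validated (shape, finiteness, simplex within 1e-6).  Gradient
access — w.r.t. adjacency entries or features — is an optional capability
needed only by the saliency/IG baselines; the linear-gradient scorer and
the search are strictly forward-only, which is what makes them applicable
to black boxes.

## Attribution

The linear gradient of an edge set is the secant slope from the base point
(targeted edges at base weight, default 0) to the data point, normalized
by `|A − A^t|`, the entrywise L1 distance over directed entries — 2w for a
single edge of weight w.  The norm is a convention: any global rescaling
leaves rankings unchanged for uniform edge weights, and per-edge it
cancels between the two directed entries.  Scores keep their sign;
negative means counter-evidence for the target class, and the target class
defaults to the model's prediction on the intact graph.

Integrated gradients uses the straight path from the all-base adjacency,
a midpoint Riemann sum with `m = 32` steps by default (exposed as a flag;
the midpoint rule also keeps path samples off the exact base point, where
a model's zero entries would hide from numeric differentiation).  The IG
edge score is reported *normalized by the edge's own L1 baseline distance*,
i.e. as an average slope along the path.  This makes the three scorers
dimensionally commensurable and gives the clean identity that IG equals
the linear gradient exactly, at any step count, for any predictor affine
in edge weights.  Saliency (SA) uses the absolute local gradient summed
over the edge's two directed entries, matching common saliency practice;
its known failure mode — vanishing gradients in saturated regions while
occlusion still moves the output — is exercised by a closed-form sigmoid
probe in the tests.

## Fidelity

`Fidelity+` is the drop in p(y) when the explanation's edges are removed
(the complement edge set is kept); `Fidelity−` is the drop when only the
explanation is kept; both difference probabilities, not logits, and both
evaluate edge-induced subgraphs — nodes are never deleted outright, which
would strand incident edges.  Two evaluation policies are provided.
`mask` (default) keeps all n nodes and zeroes removed edges' weights: it
is consistent with the weight-0 baseline convention and never produces an
empty graph.  `induce` drops nodes left without incident edges, matching
strict edge-induction semantics.  For models whose readout is unaffected
by isolated nodes the two coincide; for mean pooling they genuinely
differ, which is why the choice is surfaced rather than hidden.

## Search

Candidates are the prefixes of the score ranking (descending score, ties
to the lower edge id).  The default size range is k = 2 .. |E|−1, the
pseudocode convention for the algorithm; `k_range="full"` gives
k = 1 .. |E| and is what the evaluation harness uses so that every
fixed-size baseline prefix is among the searched candidates (making the
searched-dominates-fixed guarantee exact and per-instance).  Graphs with
fewer than four edges have an empty default window and fall back to the
full range.  Ties in the best overall fidelity resolve to the smallest k —
the sparser explanation.  The intact-graph prediction is computed once and
shared by both phases, so a linear-gradient explanation costs exactly
`1 + |E| + 2·max(0, |candidates|)` forward passes; the tests assert this
closed form and its slope of 3 in |E|.  A brute-force oracle over all
non-empty proper edge subsets (guarded to ≤ 12 edges) provides the
dominance reference for small graphs.

## Reference GNNs

Both reference architectures share the layer update
`H ← leaky_relu(P H W + b)` with a pooled linear-softmax head; they differ
in the propagation operator: `P = D^{-1/2}(A + I)D^{-1/2}` (symmetric
degree normalization, "gcn") or `P = I + A` (sum aggregation, "gin",
ε fixed at 0).  Defaults: 3 layers, hidden 32, mean pooling, full-batch
Adam (lr 1e-2) for 500 epochs, label smoothing 0.1, 80/20 seeded split;
all randomness behind the config seed, so reports are reproducible
bitwise on one platform.  Input gradients are central finite differences
(step 1e-5) over nonzero off-diagonal adjacency entries or feature
entries; parameter gradients for training are analytic.

Three training choices deserve explanation:

* **Leaky activation (slope 0.01).**  On the constant-feature motif
  benchmark the class signal at initialization is orders of magnitude
  smaller than the within-class spread; with a hard ReLU the optimizer
  collapses to a constant-output solution with exactly zero gradient
  before finding it.  The leaky slope keeps the loss surface alive.
* **Label smoothing (0.1).**  A model trained to extreme margins assigns
  probabilities so saturated that occluding a single edge barely moves
  them, and the "default" class — the one recognized by the *absence* of
  the other's motif — becomes unexplainable by any occlusion score.
  Mild smoothing keeps probabilities responsive without costing accuracy.
* **Default architecture GIN.**  With constant node features, the GCN's
  symmetric normalization cancels most degree information: a linear probe
  on random 3-layer GCN embeddings of the house-vs-cycle benchmark sits
  at ~0.53 accuracy, and a logistic fit on all diffusion statistics of
  the constant field reaches only ~0.51.  A trained GCN can still reach
  ≥ 0.98 test accuracy given ~2000 epochs (with label smoothing off — the
  uniform pull of smoothing swamps its tiny signal), but its decision
  evidence is diffuse and occlusion recovers the planted motifs poorly
  for one of the two classes (ground-truth AUC ≈ 0.68).  The GIN's sum
  aggregation preserves degrees, trains to 100% in 500 epochs, and its
  linear-gradient scores recover motifs well; it is therefore the default
  and the model used by the acceptance pipeline.

## Synthetic benchmarks

`generate_ba2motifs_like` emulates the classic house-vs-cycle benchmark
from its published description (it is an emulation, not a reproduction of
the distributed dataset): a 20-node Barabási–Albert base with attachment
parameter 1, one 5-node motif — house (6 edges, class 0) or 5-cycle
(5 edges, class 1) — attached by a single edge to a uniformly random base
node, constant 10-dimensional node features of value 0.1, classes strictly
alternating (balanced within ±1).  The ground truth is the motif's
internal edges; the attachment edge is excluded.  `generate_variable_motif`
builds 6-ring skeletons with one or two pendant nitro-like groups (center
plus two leaves, one-hot C/N/O feature codes) for positives and inert
carbon pendants for negatives, so the true explanation size varies between
instances (3 vs 6 edges) — the setting that motivates per-instance size
selection.  Both are fully seed-determined.

What these benchmarks do not emulate: chemical valence rules, edge
features, weighted/noisy edges, class imbalance, or graphs whose label
depends on global rather than local structure.  Passing the motif-recovery
gates therefore shows the pipeline recovers *localized, planted* evidence
from a well-trained model; it does not certify behavior on real molecular
data, where model quality and evidence diffusion vary.

## Evaluation protocol

Fidelity-vs-sparsity curves average Fidelity+/− of fixed-sparsity prefix
explanations over a graph set at levels {0.5, …, 0.9} by default (a
sparsity target converts to k = round((1−s)|E|), clamped to ≥ 1 edge).
The augmentation comparison reports, per scorer, the fixed-level means,
the mean with the search choosing each graph's size from the same ranking,
and the worst per-graph margin between the two.  Ground-truth ranking
quality is ROC AUC (midrank tie convention, via scikit-learn), defined
only when a graph has both positive and negative edges.  The acceptance
script runs this protocol at 300 training graphs and 50 held-out graphs —
sizes at which training takes well under two minutes on a single core
while the stochastic gates are stable across seeds.

## Known limitations

* Dense n×n adjacencies throughout: appropriate for molecule-sized graphs
  (tens of nodes), not for large sparse graphs.
* Numeric input gradients for the reference GNNs cost 2 forward passes
  per entry; fine at benchmark scale, slow for large graphs — bring an
  analytic-gradient predictor for `sa`/`ig` at scale.
* Node-classification explanation, edge-feature models, and directed
  graphs are out of scope.
* The exhaustive metrics (`exhaustiveness`, `brute_force_best_subset`)
  are enumeration-guarded and exist to validate the method on small
  graphs, not as production tools.
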