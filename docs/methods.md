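# Methods

## Model and procedure

`dlplink` scores a candidate cross-partition link (u, v) of a bipartite
network G from the path-induced subgraph around the pair.

**Extraction.** Connecting paths are simple u→v paths with exactly
2k + 1 edges, found by depth-first search with a visited set; bipartite
parity forces odd lengths, and k = 1 (3-hop paths) is the shortest
indirect connection between partitions. The direct edge (u, v), when it
exists, is excluded from traversal — not merely deleted afterwards — so
positive and negative pairs are processed by literally the same code
path and the label cannot leak into the evidence. The structure is the
subgraph of G induced on the union of path nodes plus the two targets,
minus the target edge. A pair with no qualifying path yields the
degenerate two-node, zero-edge structure rather than an error: negative
pairs in sparse networks must still receive a score.

The depth parameter admits a second, literal reading in which a "k-hop"
path has exactly k edges; under it k = 1 denotes the removed target edge
itself and every structure degenerates. Both readings are implemented
(`literal_hops=True` exposes the literal one); the 2k + 1 mapping is the
default because it is the only one under which depth-1 structures carry
any information.

**Labeling.** Node attributes are assumed unavailable. Type labels are
U → 0, V → 1. Hop labels are the distance, inside the structure, to the
nearer of the two targets; the targets themselves get 0, and no other
node can (making targets identifiable), while any node on a qualifying
path is within k hops of one target (midpoint argument on a
length-(2k + 1) path). Labels are one-hot encoded and concatenated to a
(k + 3)-vector; hop values are capped at k so the dimension depends on k
only and one model serves structures of every size. The
minimum-over-both-targets convention resolves the ambiguity of measuring
distance "to the target" when there are two targets; it is symmetric in
u and v and keeps the feature dimension small.

**Scoring.** Features are linearly projected to hidden dimension d, then
L rounds of graph convolution update each node as
h_i ← ReLU(h_i + Σ_{j∈N(i)} W_l h_j). The self-term is unweighted, which
requires all layers to share one width d — hence the separate input
projection, the minimal addition that makes the update well-typed. One
weight matrix per layer is shared by all neighbors; a per-neighbor
weight cannot be shared across structures of varying size. The structure
representation is the elementwise mean of final node states (permutation
invariant, size independent), and the link score is σ(w·H_ls) with a
logistic σ so that scores live in (0, 1) and are directly comparable to
0/1 existence labels under squared error. No dropout or normalization
layers are used, and the readout carries no bias term: with all weights
zero every score is exactly 0.5, a useful calibration reference.

**Training.** Mean squared error over the evaluated pair set, minimized
by minibatch SGD with momentum and weight decay (PyTorch update
semantics: decay added to the gradient, then velocity update, then
step). Gradients are accumulated per structure over each batch —
structures have different sizes, so there is no padded batching — and
all forward/backward algebra is explicit dense numpy, verified against
central finite differences; the graphs involved are far too small for
sparse or accelerated kernels to pay off.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 1 | structural depth; connecting-path length 2k + 1 |
| hidden_dim d | 32 | width of all GCN layers |
| num_layers L | 2 | graph-convolution rounds |
| lr / momentum / weight_decay | 1e-2 / 0.9 / 1e-5 | SGD settings |
| epochs / batch_size | 80 / 5 | training schedule |
| test_fraction | 0.2 | held-out edge share (round half away from zero) |
| path_cap | 10 000 | per-pair path budget; logged warning when hit |
| p_in / p_out | 0.25 / 0.02 | generator block edge probabilities |
| n_u × n_v | 40 × 40 | generator partition sizes, two equal blocks |

The optimizer settings and schedule are the conventional choices for
this family of small-graph scorers; depth and width are sized to
desk-scale affiliation networks (hundreds of candidate pairs, structures
of 2–40 nodes). Generator defaults emulate small dense affiliation
networks: ~216 expected edges, mean degree ≈ 5.

## Evaluation protocol

20% of edges are removed uniformly as positive test pairs; equally many
distinct non-edges are sampled uniformly as negatives, split so that
train and test negatives match their positive counterparts in number.
Negatives are drawn once per split, not resampled per epoch, matching a
static training-set construction. Every structure — training and test —
is extracted from the training graph (observed network minus test
edges); extracting test evidence from the full graph would leak the
held-out edges, and a guard test asserts the two differ. MAE and RMSE
compare sigmoid scores to 0/1 labels directly, without thresholding, as
regression metrics; MAE ≤ RMSE always (power-mean inequality). The MSE
objective's normalization is taken over the evaluated pair set rather
than the full n×m matrix, consistent with training on sampled pairs.

## What the generator does and does not emulate

The planted model draws each U×V pair independently with probability
p_in inside matched blocks and p_out across. Matched-block pairs are
therefore embedded in a dense sub-biclique with many 3-hop connections —
the qualitative signal that local structure is meant to capture — and
the generated densities sit in the regime of small real affiliation
datasets.

Two consequences of the independence assumption matter when reading
results on this generator:

* **An information ceiling.** Conditional on block co-membership, edge
  indicators are i.i.d., so once the target edge is removed the local
  structure is independent of the label given co-membership. The best
  any structure-based scorer can do is infer co-membership and output
  the calibrated posterior. On a balanced test set with the default
  parameters that posterior is ≈ 0.68 for within-block pairs and
  ≈ 0.11 for cross-block pairs, putting even a perfect co-membership
  oracle at RMSE ≈ 0.43 — far above 0 — and the structure reveals
  co-membership only noisily (a within-block pair has no surviving
  3-hop path in roughly a fifth of cases after the 20% holdout).
  Observed RMSE near 0.5 on the default generator therefore reflects
  the generator's ceiling at these settings, not necessarily a failure
  of the scorer; sharper block contrasts (larger p_in/p_out ratio)
  raise the ceiling.
* **No depth penalty.** In real affiliation networks, deeper path
  neighborhoods blur the distinction between candidate pairs and
  shallow structures discriminate best. Under independent-Bernoulli
  blocks the reverse can hold: length-7 paths exist for almost every
  pair, and their abundance grades co-membership more smoothly than the
  often-empty depth-1 evidence. Passing or failing a depth comparison
  on this generator says little about depth behavior on real data.

Real data also exhibit degree heterogeneity, transitivity and
community overlap that the generator omits. Green pipeline tests on
synthetic networks certify the machinery — extraction correctness,
leak-freedom, reproducibility, calibration floors — not real-world
accuracy.

## Numerical choices

* Split sizes round half away from zero; the remainder stays in
  training. File node ids map to dense 0-based indices in sorted-id
  order; all iteration over sets is in sorted order, so every stage is
  deterministic given its seed.
* A single run seed fans out to independent sub-seeds (split, negative
  sampling, initialization, shuffling) via `numpy` seed sequences, so
  stages can be re-run in isolation and CLI outputs are byte-identical
  across repeats.
* Initialization is uniform Glorot-style per array; unreachable nodes
  (impossible by construction, handled defensively) get sentinel hop
  k + 1, folded into the cap.
* Path enumeration prunes on BFS distance to the far target (a node
  that cannot reach v in the remaining edges is skipped) and stops at
  `path_cap` paths with a logged warning; worst-case path counts grow
  exponentially, though capped pairs are rare at desk scale.
* The loss of a trailing short batch is averaged over its true size.

## Limitations

* Exhaustive simple-path enumeration is exponential in the worst case;
  the cap bounds time at the cost of truncating extremely dense
  structures (flagged on the structure record).
* Unweighted, static, strictly bipartite networks only; no node
  covariates, no temporal information, no multigraphs.
* CPU-only by design; training cost grows linearly with the number of
  candidate pairs and quadratically with structure size, comfortable up
  to a few thousand pairs.
* Scores are calibrated only relative to the sampled negative
  distribution; they are not absolute link probabilities.
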