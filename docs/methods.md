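# Methods

## Problem and model

The package implements node classification on a gene-interaction graph for
disease-gene risk prioritisation. The data model is a graph G = (V, E, C):
nodes V are genes appearing in a protein-interaction network (PIN), edges E
are reported physical interactions (undirected, deduplicated, no
self-loops), node features are one-hot (or multi-hot) chromosome-band
locations taken from a curated risk catalogue, and C is one of three label
sets over the same nodes:

* **binary** — a gene carries risk (it appears in the catalogue with a
  confidence score) or it does not;
* **multiclass** — no / low / moderate / high association, mapping catalogue
  confidence scores 3/2/1 (1 = most confident) onto low/moderate/high;
* **syndromic** — whether the catalogue flags the gene as syndromic.

Genes present in the interaction network but absent from the catalogue get
the background class and a reserved "unknown" band indicator. The score→class
mapping follows the catalogue's own ordering (score 1 is the most confident
association, hence "High Association"); with the full-scale catalogue shape
this yields 214 high + 530 moderate + 69 low = 813 binary positives against
11,403 unassociated genes, and a 169 / 12,047 syndromic split — counts the
acceptance checks recompute.

## Classifier families

Four families share a common shape (two representation layers with ReLU, a
linear head, log-softmax output) and a common training regimen:

* **GCN** — propagation h_v' = σ( Σ_{u∈N(v)} (1/c_v) W h_u ), with row
  (c_v = deg v) or symmetric (c_v = √(deg v · deg u)) normalisation and
  optional self-loops. The default is self-loops + symmetric normalisation,
  because the bare rule discards a node's own features; the literal form
  (no self-loop, c_v = deg v) is available and is what the oracle tests
  exercise.
* **GraphSAGE** — the neighbour mean (or sum) is concatenated with the
  node's own embedding, then linearly transformed: h_v' = σ(W·[h_v ‖
  mean_{u∈N(v)} h_u]). Isolated nodes aggregate a zero vector.
* **Graph transformer** — all-pair attention: each layer maps embeddings to
  queries/keys/values and computes z_u' = Σ_v softmax_v(q_u·k_v) v_v. The
  kernelized variant (the default) replaces the softmax kernel with a
  nonnegative feature map φ so the two global sums Σ_v φ(k_v)v_vᵀ and
  Σ_w φ(k_w) are computed once and shared across nodes, making the layer
  linear in node count. φ defaults to positive random features
  (φ(x) = exp(Wr x − ‖x‖²/2)/√m, Wr Gaussian, seeded), which approximate the
  exponential kernel with error decaying in the feature count m; an exact
  `exp` map (for the 1-D/constant-query case) and `elu+1` are available.
  A literal stack of attention layers on raw features is untrainable — at
  initialisation the attention is near-uniform, every node receives the same
  global value mean, and the loss sits at ln C — so the family uses an input
  projection to the hidden width and a residual connection around each
  attention block, the standard components of the kernelized-transformer
  lineage it follows. No Gumbel edge sampling, relational bias or multi-head
  attention is included.
* **MLP baseline** — three dense layers on node features alone; the
  network-blind reference point.

All numerics run on an in-package reverse-mode autodiff over NumPy arrays
(`genegraph.autodiff`), verified against finite differences; sparse
adjacency products are handled as constant-matrix operations.

## Class balancing and splitting

Minority classes are upsampled to the majority count by sampling source
nodes with replacement. A duplicate takes its source's feature row and its
full adjacency row/column — the balanced adjacency is exactly
`A[ix][:, ix]` for the index vector `ix = originals + sampled sources` — so
duplicates inherit every neighbour of their source, are not linked to the
source itself, keep the source's degree, and never alter edges among
original nodes. An `interpolate` mode (convex mix with a same-class
neighbour's features, in the spirit of graph-SMOTE) is available but not the
default, since literal duplication is what the reproduced protocol
describes.

Two split protocols are exposed. `after_upsample` (default,
protocol-faithful) stratifies the *balanced* node set into 75/25 train/test;
duplicates of one gene can then straddle the split, which leaks information
— metrics under this protocol are optimistic, and reports therefore also
include an originals-only evaluation. `before_upsample` is the leakage-safe
alternative we recommend for real use: originals are split first and only
training-side nodes are eligible duplication sources.

## Training regimen

AdamW (decoupled weight decay) minimising the NLL of log-softmax outputs on
training nodes. Defaults: learning rate 0.001, weight decay 5e-4, epsilon
1e-4 (interpreted as the optimiser's numerical-stability constant), 5000
epochs. Graph families train full-batch — full-graph message passing makes
mini-batching meaningless for them, so the batch-size setting (64) is
honoured only by the MLP, which trains on true shuffled mini-batches. Early
stopping exists (`patience`) but is off by default. Training is
deterministic given the seed; a non-finite loss aborts with a diagnostic.

## Synthetic cohorts

The generator emulates the statistical shape of the catalogue + PIN join so
the pipeline can be validated without any download:

* exact class counts (default 214/530/69/11,403, 169 syndromic; `scaled(f)`
  shrinks everything by `f`, e.g. `scaled(10)` → 1,222 genes, 21/53/7/1,141);
* a cytoband-style vocabulary (default 471; scaled alongside the cohort).
  10% of it is reserved as risk-enriched loci, split into disjoint per-class
  subsets; a risk gene draws its band from its class subset with probability
  `band_signal` (default 0.8), else uniformly. Each gene gets one band;
  multi-band records are supported by the parser but not planted;
* a degree-corrected planted partition for edges: node propensities are
  log-normal (σ = 0.75) so hubs resemble a real PIN; a pair in the same risk
  class multiplies the base rate by `homophily` (default 5), a pair in two
  different risk classes by (1+homophily)/2, background pairs by 1. The base
  rate is calibrated in closed form to the target mean degree (default 8);
* syndromic flags drawn preferentially from risk genes, so the syndromic
  task inherits part of the planted structure;
* ~5% decoy interaction rows under non-human species annotations, to
  exercise the filtering step.

What the generator does **not** emulate: real gene symbols and band
frequencies, the true (unreported) degree distribution and homophily of the
source networks, assortativity beyond the class blocks, and any correlation
between band location and network topology. Passing tests therefore show
that the pipeline recovers *planted* signal of the stated kind and
strength; they do not certify accuracy on the real catalogue, whose
headline numbers (85.80% binary, 81.68% multi-class, 90.22% syndromic in the
source experiment) depend on unreleased data snapshots and are treated as
aspirational context only.

## Evaluation

Per-class specificity TN/(TN+FP) and sensitivity TP/(TP+FN) (one-vs-rest
for multiclass), accuracy as a percentage, and two F1 conventions printed
side by side — positive-class F1 for two-class tasks, macro F1 for the
four-class task — because the convention in the reproduced tables is not
stated. ROC curves are computed one-vs-rest from softmax confidences; the
operating threshold maximises Youden's J = sensitivity + specificity − 1
with ties broken toward higher specificity. Curve AUC is checked against the
rank-statistic (concordance) formulation. Classes absent from a test set
report NaN rates, never 0. Ranked "top-k confidence" gene lists take the k
highest-confidence *predicted* members of a class among original
(non-duplicate) nodes. t-SNE projections of penultimate-layer embeddings are
seeded and guarded against too-large perplexity.

## Experiment sizes and numerical choices

The seed-replicated ordering study — the package's acceptance-level claim —
uses 20 paired seeds of the `scaled(10)` cohort (≈1,222 genes), homophily 5,
band signal 0.8, the binary task, and a shortened schedule (150 epochs at
learning rate 0.01, hidden width 32): loss traces plateau well before epoch
50 at this scale, and the larger step compensates for the shorter schedule.
Within a seed every variant sees the identical graph and split, so
comparisons are paired; orderings are asserted on means over seeds plus a
one-sided paired sign test at p < 0.05. The featureless ablation replaces
features with a constant column by default (an identity/one-hot surrogate is
available but quadratic in node count).

Degenerate inputs are handled explicitly: empty interaction lists and empty
classes are errors; isolated nodes propagate zero messages (logged);
kernelized attention raises if the feature-map denominator underflows;
duplicate catalogue symbols collapse to the best-scored record with a
warning. Stage seeds (generation, split, initialisation, projection) are
fanned out from one global seed via `SeedSequence`, all below 2^31.

## Known limitations

* The protocol-faithful split leaks duplicated genes across train/test;
  numbers under it overstate generalisation (originals-only metrics are
  emitted alongside).
* Band features enter only through the catalogue; in real use genes outside
  the catalogue would need an external cytoband annotation to receive
  informative features.
* The transformer omits the relational-bias and edge-sampling components of
  its lineage; on small homophilous graphs it generally trails GraphSAGE.
* No hyperparameter search or cross-validation; a single stratified split
  per seed, as in the reproduced protocol.
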