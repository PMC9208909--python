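# Methods

## Glycans as graphs

Glycans are the only nonlinear biological sequence class: branched trees
of monosaccharides joined by glycosidic linkages.  `glyconet` models a
glycan as an undirected tree in which **both monosaccharides and
linkages are nodes**.  Treating linkages as nodes (rather than edge
attributes) keeps minimal structures representable — the Tn antigen
`GalNAc(a1-` is a monosaccharide plus a dangling, degree-1 linkage node
— and lets one embedding table cover the whole token vocabulary.

The parser consumes IUPAC-condensed notation (linkages in parentheses,
branches in square brackets, reducing end rightmost).  Normalization
maps Greek α/β to a/b, en/em dashes to `-`, and strips whitespace,
because public glycan data mix these freely.  Any bracket-free run
between linkages is one monosaccharide token, so modified sugars
(`GlcNAc6S`) stay whole.  A trailing unclosed linkage is the only legal
dangling linkage; all other imbalances raise a parse error with a
position.  Unknown tokens at inference map to `<unk>` rather than
erroring, so models can score glycans containing monosaccharides (e.g.
Kdo) absent from training.

Motifs of length k ≤ 3 are linear chains of k monosaccharides with
their intervening linkages, written non-reducing → reducing end
(`Neu5Ac(a2-3)Gal`).  Dangling linkages contribute no k ≥ 2 motifs: a
motif requires two monosaccharides.

## The 42 structural graph features

`graphfeat` computes a fixed, documented 42-feature vector per glycan:

* 11 scalars: `num_nodes`, `num_node_types`, `diameter`,
  `branching_number` (nodes with ≥ 3 neighbours), `num_leaves`,
  `degree_assortativity`, `nodes_with_degree_ge4`,
  `max_leaves_per_node`, `mean_leaves_per_node`, `kcore2_size`,
  `corona2_size`.
* {max, min, mean, variance} of 7 node centralities (28 features):
  betweenness, closeness (normalized by n−1), harmonic (unnormalized
  Σ 1/d), eigenvector (power iteration, tol 1e-8, ≤ 1000 iters), load,
  second-order (analytic random-walk return-time spread, not
  simulation), and current-flow betweenness.
* {max, mean, variance} of edge current-flow betweenness (3 features).

Degree centrality is omitted as a 4-aggregate measure because degree
information is already carried by the five degree-derived scalars; the
minimum of edge flow is omitted because on trees it is pinned to the
pendant edges and nearly constant.  Undefined quantities take a
documented `0.0` sentinel: assortativity on regular/star graphs,
centralities of a single node, the variance over one element, and every
k-core/k-corona with k ≥ 2 — which on trees (|E| = |V|−1) is always
empty, so `kcore2_size = corona2_size = 0` by construction.  All
centralities are computed with networkx; correctness is checked against
exhaustive shortest-path brute force on every tree with ≤ 7 nodes.

The feature-based baseline is a random forest (100 trees, seeded) on an
80/20 stratified split, reporting held-out accuracy and normalized
impurity importances.

## SweetNet

The classifier embeds each node token in 128 dimensions and applies
three blocks of: graph convolution → leaky ReLU (slope 0.01) → TopK
pooling (ratio 0.5) → readout.  The default operator is GraphConv
(`x_i W1 + Σ_{j∈N(i)} x_j W2 + b`); SAGEConv (mean aggregation) and
SGConv (symmetric-normalized propagation) are drop-in alternatives
behind the same interface.  TopK pooling scores nodes by `x·p/‖p‖`,
keeps the top ⌈ratio·n⌉ per graph and gates kept features by tanh of
their score, so the score vector trains through the selection.  The
readout concatenates global mean and global max over surviving nodes
(2 × 128 = 256 dims); the three per-block readouts are **summed** into
the glycan representation.

The fully connected head is 256 → 128 (linear → batch-norm →
leaky ReLU → dropout 0.2), then a boom layer as the middle FC layer
(128 → 512 → 128, expansion 4), then the output layer under
multi-sample dropout: 8 independent dropout masks of the penultimate
activation pass through the final linear layer; losses are averaged
during training, and at inference dropout is off so a single pass is
used.  The fixed intra-layer order is linear → batch-norm →
leaky ReLU → dropout.  Representations for downstream analyses are
taken directly before the FC head.

Weights use sparse initialization: in every 2-D weight matrix, 10% of
the incoming entries per output unit are nonzero Gaussian (scaled
1/√k for k nonzeros, keeping unit output variance), the rest exactly
zero.  Embeddings and biases are excluded.

## Optimization

Adam with weight decay 0.001 (classic L2), base learning rate 5e-4
decayed by `lr(e) = base · ½(1 + cos(π·min(e,T)/T))` with T = 80, at
most 100 epochs, batch size 32, early stopping after 20 epochs without
improvement of the monitored loss.  The raw cosine reaches 0 at epoch
80, which would freeze epochs 81–100; a floor of 1e-6 keeps them
active.  The monitored loss is validation loss when a validation split
exists, else training loss; the best-loss checkpoint is restored.
Losses: cross-entropy (multiclass), binary cross-entropy, or mean
squared error (regression).

Dataset splits are stratified 80/20 with classes of fewer than 5
members removed and a per-class test count of `max(1, round(0.2·n))`,
so every surviving class appears in the test set.

Context pretraining masks one uniformly chosen node per glycan with
`<mask>` and predicts its token with a linear decoder over the node's
embedding after the three conv layers.  Pooling is disabled for this
pass — TopK discards nodes, which would make the masked node's
embedding undefined.  Single-node glycans are skipped with a warning.

## Representation analyses

Glycan representations (2 × embed_dim, eval-mode deterministic) feed:
a logistic-regression probe (80/20 split, seeded), K-means cluster
agreement via the adjusted Rand index (10 restarts; exact
contingency-table chance correction), and phylogenies: per-taxon
arithmetic-mean vectors (taxa under a minimum glycan count are
excluded), cosine distance `1 − u·v/(‖u‖‖v‖)`, and agglomerative
clustering.  Average linkage (UPGMA) is the default — the standard
choice for distance-matrix phylogenies — and configurable.  Trees are
exported as Newick with branch lengths of half the merge-height gap, so
leaf-to-root path lengths equal merge heights under ultrametricity.

## Protein–glycan binding

Glycan-array readouts are standardized per array: z = (x − mean)/sd
with the sample (n−1) standard deviation; arrays with fewer than two
measurements or zero variance are rejected by name.  Hemagglutinin
inputs use the core slice covering the receptor-binding loops, 1-based
residues 50..300 inclusive (251 residues), when the sequence is
full-length; shorter (partial) sequences pass through unchanged so
partial-sequence screens remain comparable.

The joint model encodes the label-encoded core sequence with a
single-layer unidirectional LSTM (hidden 128; the final hidden state is
the protein representation) and the glycan with either (a) the vector
of mono/di/tri-saccharide motif counts through a dense layer, or (b)
the SweetNet trunk — both projected to 32 dims.  The two
representations are concatenated and a dense head (32 hidden units,
dropout 0.3) regresses the Z-score under MSE.  The motif index is built
from training glycans only, avoiding leakage.  Dropout of 0.2 is also
applied to the motif-count vector during training: trisaccharide counts
nearly identify individual glycans, and input dropout discourages the
head from memorizing per-glycan noise instead of the shared motif
signal.  Records split 80/20 at random by default; `split_by="array"`
holds out whole arrays for stricter generalization.  15% of training
records monitor early stopping.

Diagnostics: residuals z_obs − z_pred with global and per-group
(host, subtype) MSE tables, and per-unique-sequence LSTM
representations.

## Motif enrichment

Per host, glycans are called predicted binders when the predicted
Z-score strictly exceeds 1.645 (one-sided normal 95% point, the
convention for glycan-array calls).  For each motif, the 0/1 presence
indicator is compared between binders and non-binders with a one-tailed
Welch's t test (binders greater) — the prevalence reading of
"more common among predicted binders"; testing predicted-Z
distributions per motif is a defensible alternative we did not adopt.
Degenerate inputs take sentinels: both variances zero with equal means
→ t = 0, p = 1 (a motif present everywhere discriminates nothing);
unequal means → t = ±∞ with p ∈ {0, 1} by sign.  Holm-Šidák
(step-down `1 − (1−p)^(m−i+1)` with a running maximum) corrects within
each host; significance is adjusted p < 0.05; motifs are ranked by
adjusted p with ties averaged (adjusted p is the thresholded quantity,
so it is also the ranking key); the summary reports each motif's median
rank across hosts where it is significant.  Motifs observed in few
glycans are still tested.  Hosts with fewer than two binders or two
non-binders are skipped with a warning.

## Synthetic data

The generator emulates curated glycan corpora and array panels, not
biosynthetic reality (no enzyme constraints, no real-world motif
frequencies — passing tests show the machinery recovers planted
structure, not that it matches any organism's glycome):

* Glycans: random rooted trees over 12 common monosaccharides and 8
  linkages, 3–8 monosaccharides, ≤ 2 children per node, branch
  probability 0.25 per attachment (typical arborescence of N/O-glycans);
  rendered to IUPAC-condensed with first child unbracketed and later
  children bracketed.  Every generated string round-trips through the
  parser.
* Classification: positives get the rule motif written onto a random
  root-ward chain; negatives are rejection-sampled motif-free.
* Binding: two protein families (independent random ancestors of 60
  residues, members 5% point-mutated — family identity is trivially
  visible to the LSTM, as hemagglutinin subtypes are), one array per
  protein, 16 proteins, 120 glycans, and
  `z = 2.5·[glycan contains the family's motif] + N(0,1)`.  The panel
  is designed, not sampled: exactly 30% of glycans carry each family's
  motif (exclusively), the rest neither, mirroring the controlled
  composition of printed arrays and giving a null-predictor MSE of
  `2.5²·0.21 + 1 ≈ 2.3`.  Sixteen proteins give ≈ 6–7 training
  replicates per (glycan, family) cell, enough that held-out records
  are predictable from the shared motif rule.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use: 10,000 glycans for
parser invariants; all 45 trees with ≤ 7 nodes for feature oracles; 100
random sample pairs (1e-12 agreement) and 50 null replicates × 200
motifs for the statistical oracles; 625 glycans (500 train) for the
planted-rule task; the 16 × 120 panel (1,920 records) for binding; 12
synthetic species for phylogeny recovery.  All computation is float64
on CPU; forwards in eval mode are bit-deterministic, and every source
of randomness flows through seeded `numpy` generators.

Known limitations: the NN stack is a compact reverse-mode autodiff over
numpy written for this package — correct (gradient-checked) but not
fast; realistic corpus-scale training (tens of thousands of glycans,
hundreds of classes) is out of reach at desk scale, which is why the
tests assert recoverable planted structure rather than published
benchmark numbers.  Canonicalization of isomorphic branch orderings is
not attempted (deduplication is by normalized string), and repeat-unit
notation (`{...}`) is unsupported.
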