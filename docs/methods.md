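# Methods

## Problem and model

Protein subcellular localization is treated as multi-label, multi-class
classification: a protein carries one or more location labels from a
fixed vocabulary (e.g. the 12 human compartments: centrosome, cytoplasm,
…, plasma membrane). The predictor is a hybrid of a convolutional feature
extractor and boosted decision trees, staged as encode → CNN → features →
binary-relevance boosting → threshold.

### Similarity-profile encoding

Each protein is encoded as an *L*-vector of similarities to the *L*
training proteins, in an order frozen at fit time. The sequence
similarity backend is pluggable:

- **k-mer cosine** (default, k = 3): cosine similarity of overlapping
  k-mer count vectors. Out-of-vocabulary query k-mers contribute nothing
  to the dot product but still count toward the query norm, so the value
  is the true cosine over the full k-mer space. A zero-norm profile is
  assigned similarity 0 with a warning, keeping every vector defined.
- **PSSM cosine**: cosine similarity of the column-averaged rows of two
  proteins' position-specific scoring matrices (20-vectors), rescaled
  affinely from [−1, 1] to [0, 1]. Any conforming PSI-BLAST ASCII file is
  accepted; the package does not run PSI-BLAST.

An optional interaction score matrix (precomputed; e.g. STRING scores,
possibly already folded together with ontology-derived similarities by
the user) enters as a convex combination
`α·seq + (1−α)·ppi`, with α forced to 1 when no matrix is supplied.
The combination rule, the backends and α itself are design choices of
this package: only the shape of the representation (similarity-to-
training-set profile) is fixed by the approach being implemented, not
the formula for its entries.

### CNN feature extractor

Architecture: repeated conv1d → ReLU → max-pool blocks, a stack of
fully-connected ReLU layers, and a linear output layer with one logit
per location. Defaults: two blocks (16 filters, kernel 5, pool 2;
32 filters, kernel 5, pool 2), hidden widths (64, 32) — so features are
32-dimensional — Adam at learning rate 1e-3, 30 epochs, batch 32. The
source method reports no depth, filter counts, optimizer or epochs;
these defaults are a LeNet-scaled choice small enough for desk-scale
data. Training minimizes multi-label BCE over sigmoid activations (the
default), computed in the stable `max(f,0) − f·y + log(1+exp(−|f|))`
form; softmax cross-entropy with the label set normalized to a target
distribution is retained as an option for single-label corpora. After
training, the output layer is discarded and the last hidden layer's
post-ReLU activations are the features.

The network is implemented directly in numpy (forward and backward
passes, Adam). This keeps the dependency surface small and makes
training bit-reproducible: all randomness (He-normal initialization,
epoch shuffling) flows from one `numpy` generator seeded by the config,
and the arithmetic is single-threaded.

### Second-order boosted trees

For each location an independent binary ensemble is fit to the CNN
features (binary relevance). Each round evaluates the logistic-loss
derivatives at the current margins, g = σ(m)−y and h = σ(m)(1−σ(m)),
and grows a regression tree greedily, one level at a time, to
`max_depth`:

- every feature and every midpoint between consecutive distinct sorted
  values is a candidate split;
- a split's gain is ½[G²_L/(H_L+λ) + G²_R/(H_R+λ) − G²_P/(H_P+λ)] − γ;
- a node stays a leaf when the best gain is ≤ 0 or a child's hessian sum
  would fall below `min_child_hessian`;
- leaves receive w = −G/(H+λ);
- ties break toward the lowest feature index, then the lowest threshold.

The prediction is `base_margin + learning_rate · Σ trees`, with the base
margin the training log-odds clipped to [1/(n+2), (n+1)/(n+2)] so
all-constant label columns stay finite. Defaults: 100 rounds, shrinkage
0.3, depth 3, λ = 1, γ = 0, `min_child_hessian` = 1e-3. Shrinkage and
the base margin are standard boosting practice rather than part of the
published derivation, which gives only the per-tree optimum.

Numerical detail: split candidates are screened with a prefix-sum scan
(O(n log n) per feature), and the near-best candidates are re-scored
with direct sums over the actual partitions before the final comparison.
This makes the selected split — and therefore the whole tree —
independent of floating-point accumulation order, so the greedy grower
agrees exactly with a naive brute-force enumerator under the same tie
rules. No histogram approximation, subsampling or sparsity handling is
implemented; at the feature dimensions the CNN produces, exact greedy
enumeration is affordable.

The notation of the published derivation swaps the roles of the first-
and second-derivative sums between its definition and its leaf-optimum
formula, and once prints the leaf-count penalty with the wrong symbol;
this implementation uses the standard convention (gradient G, hessian H,
w = −G/(H+λ), penalty γ per leaf), which is the only reading under which
the quadratic is minimized by the stated optimum.

### Decision rule

Per-location probabilities ≥ threshold (default 0.5, the binary-
relevance convention) form the predicted set; an empty set falls back to
the argmax location, since in the datasets this method targets every
protein has at least one localization. The source method does not state
how probabilities become label sets; this rule is our choice.

## Evaluation

- **ACC-mean**: per-protein Jaccard index |T∩P| / |T∪P| (equivalently
  TP/(TP+FP+FN) on label sets), averaged over test proteins. Empty truth
  is an error; an empty prediction against non-empty truth scores 0.
- **Per-location precision/recall/F1**: precision averages, over the
  proteins *predicted* at location j, the per-protein ratio TP/(TP+FP);
  recall averages TP/(TP+FN) over the proteins *truly* at j; F1 is their
  harmonic mean (0 when both sides are 0). The published formula is
  typographically ambiguous about where |P_j| sits; the mean-over-
  proteins reading used here is the only one producing values in [0, 1].
- A location never predicted (or never true) has undefined precision
  (recall), reported as NaN with the counts alongside, and F1 = 0 —
  undefined is deliberately distinguished from a genuine zero.
- **F1-mean**: unweighted mean of per-location F1 over locations present
  in truth or predictions. Note that macro means computed this way need
  not match a table whose summary row was derived differently; the macro
  definition is documented here and used consistently.

## Synthetic data

The generator emulates curated multi-label localization corpora (more
labels than proteins, a fixed location vocabulary) at desk scale. Each
location receives one fixed random motif; each protein draws one
location uniformly (plus a second, distinct one with probability
`multilabel_prob`), a background-sampled sequence, and — per label, with
probability `motif_insert_prob` — the label's motif overwrites a
uniformly chosen window. Everything derives from one seed.

Defaults are the benchmark condition used throughout: 300 training /
100 test proteins, 4 locations, 5-residue motifs inserted with
probability 0.95, 30% second-label probability, uniform amino-acid
background. Sequence lengths are drawn from 60–120 residues — scaled
down from typical protein lengths so a single short motif remains
detectable in a k-mer cosine profile at desk-scale training sizes. The
interaction-matrix generator draws clipped-normal scores with a higher
mean for label-sharing pairs; the PSSM stub gives each residue a
dominant score in its own column.

What the generator does *not* emulate: realistic amino-acid composition,
signal peptides and sorting signals with positional structure, homology
between proteins, or label correlations beyond an independent second
draw. Passing the synthetic benchmark therefore shows that the pipeline
can extract planted, location-linked sequence signal end to end — not
that it attains any particular accuracy on real proteomes, which would
additionally require the original curated datasets and their
interaction/ontology feature sources.

## Problem sizes and runtime

The benchmark condition (300 train / 100 test, default CNN and boosting
settings) trains in well under a minute on one CPU; the test suite uses
a smaller pipeline (one conv block, 25 boosting rounds, 60 training
proteins) for workflow tests and reserves the full condition for the
acceptance checks. Oracle-equivalence checks run on instances of at most
20 points and 3 features, where brute-force enumeration is exact and
fast.

## Known limitations

- The k-mer and PSSM-average similarities are bag-of-residue measures;
  they ignore motif position, which the conv layers can only partially
  recover from profile structure.
- Binary relevance ignores label correlations by construction.
- The CNN sees training proteins in an arbitrary (input) order along the
  profile axis; convolution exploits only local structure in that
  arbitrary order, so most of the signal is carried through the
  fully-connected layers.
- Model bundles embed full encoder state (the training-set profiles), so
  bundle size grows with the training set.
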