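# Methods

`hetdti` predicts drug–target interactions (DTIs) by combining string-level
similarity of drugs and proteins, a heterogeneous graph over both node
types, a hybrid graph-convolution/graph-attention encoder, and a random
forest scoring fused drug–protein pair representations. This note records
the model as implemented, the defaults and why they were chosen, and the
known limitations.

## Similarities

**Proteins.** Pairwise Smith–Waterman local alignment scores over the
20-letter amino-acid alphabet (unknown residues map to `X`). The scoring
matrix defaults to BLOSUM62; the gap model is affine,
`W_k = open + (k-1)·extend`, with `open = extend = 10` by default (i.e., a
linear penalty of 10 per gapped residue), implemented with Gotoh's
incremental recurrences in a numba kernel. Raw scores are normalized
row-wise, `S_P(i,j) = (SW(i,j) − min_j SW(i,j)) / (max_j SW(i,j) − min_j
SW(i,j))`, with the min/max taken over the full row *including* the
diagonal so self-similarity maps to exactly 1. Row-wise normalization is
asymmetric, so the matrix is then symmetrized by averaging with its
transpose and the diagonal reset to 1. A degenerate row (all scores equal)
becomes 0 off-diagonal with a warning. Sequences longer than 300 residues
keep their prefix.

**Drugs.** Each SMILES string is converted to a SELFIES string and split
into bracket symbols (at most 100 tokens, prefix kept). A skip-gram
word2vec model with a full-softmax objective embeds every token
(dimension 64, window 5, 100 epochs, where an epoch is one seeded
mini-batch SGD pass of batch size 1024 over all center–context pairs; full
softmax is exact and cheap at these vocabulary sizes, ~10²). A drug vector
is the arithmetic mean of its token vectors — the minimal deterministic
pooling — and `S_D` is pairwise cosine similarity clipped into [0, 1]
(cosine can be negative; the declared codomain is the unit interval). The
ablation axis `drug_encoding="smiles"` tokenizes the raw SMILES characters
(two-letter element symbols kept whole) instead.

**SELFIES codec.** No SELFIES library is part of this package's
dependency set, so `hetdti.selfies_codec` implements the v2 grammar
conventions (hexadecimal index symbols, `[BranchL]`/`[RingL]` length and
offset annotations) for a well-defined subset: uncharged organic molecules
(B, C, N, O, S, P, F, Cl, Br, I) without isotopes, radicals or stereo
annotations; aromatic systems are kekulized before encoding. Round-trips
are verified against RDKit canonical SMILES. Molecules outside the subset
raise an error rather than encode incorrectly.

## Heterogeneous network and features

With `v` drugs and `m` proteins, the network is the `(v+m)×(v+m)` block
matrix `H_DP = [[S_D, A_DP], [A_DP^T, S_P]]`, where `A_DP` is the binary
known-interaction matrix. Known drug–drug or target–target association
edges, when supplied, override the corresponding similarity entry to 1.
Node features are initialized as `F_DP = H_DP` (each node's feature vector
is its adjacency row), so the feature dimension equals `v+m`. Similarity
blocks are kept dense — no thresholding — at the network sizes this
package targets.

During evaluation, `A_DP` is rebuilt per fold from that fold's *training*
positives only; validation and test interactions are absent from the
matrix the encoder sees (verified by an explicit leakage test).

## Encoder

The default layer plan is GCN → GAT → GCN with hidden sizes (256, 128, 64).

* **GCN**: `F' = ReLU(D^{-1/2}(I + H)D^{-1/2} F W)`, the symmetrically
  normalized self-looped convolution.
* **GAT** (K = 4 heads, averaged): per head the logit for an ordered pair
  of distinct neighbors is `e_ij = LeakyReLU(a^T[W F_i ‖ W F_j]) + B·H_ij`
  with slope 0.2, where `B` is one learnable scalar per head weighting the
  edge similarity; attention is the softmax of `e_ij` over the off-diagonal
  neighborhood `{j ≠ i : H_ij > 0}` (an isolated node attends to itself),
  and the output is ReLU of the head-averaged `Σ_j φ_ij W F_j`. Heads are
  averaged, not concatenated. Self-edges participate in the GCN's
  self-loops but are excluded from attention neighborhoods.

The final matrix splits into drug rows `X_D` and protein rows `X_P`; a
pair's fused representation is the concatenation `z = [x_drug ‖ x_protein]`
(128-dimensional at the default sizes).

**Training.** A disposable scoring head provides pair probabilities; the
loss is the summed binary cross-entropy over labeled training pairs
(known interactions vs. an equal number of sampled unknown pairs) plus
`(λ/2)‖θ‖²` over all parameters, λ = 5·10⁻⁴. The default head is the
inner-product link decoder `p = sigmoid(s·⟨x_drug, x_protein⟩ + b)` with
a learnable scale and bias. This choice is load-bearing: a logistic head
on the *concatenation* `z` decomposes into independent drug and protein
propensity terms and cannot represent pair affinity, so its training
signal stays at chance and — once the data gradient is negligible —
Adam's normalized steps let the L2 term shrink the network until the
features collapse. The inner product is the minimal head whose gradient
aligns interacting pairs in embedding space; the concatenation head
remains available (`head="linear"`). The head is discarded after
training; the forest consumes `z`. Gradients come from a
small reverse-mode autodiff engine written for this package (dense numpy,
float64, finite-difference-checked in the test suite); optimization is Adam
(lr 10⁻³) by default, with plain SGD available — the monotone-descent
property test uses SGD at small step size. Training is full-graph and
full-batch, hence bit-reproducible for a fixed seed on one thread.

Defaults worth noting: **800 epochs, dropout 0**. On reference-size
problems (~140 nodes) the deterministic full-batch optimizer is still far
from its loss plateau at a few hundred epochs, and per-epoch dropout noise
prevents convergence outright while L2 already regularizes; both choices
were made from the training-loss behavior and are configurable.

## Classifier

A random forest of 200 CART trees grown on bootstrap resamples, splitting
by the Gini index `Gini_index = Σ_v (|X^v|/|X|)(1 − Σ_i p_i²)` over a
random `sqrt(d)` feature subset per node; a pair's score is the mean
positive-class leaf probability across trees, and feature importances are
normalized mean decreases in Gini impurity. The ensemble is backed by
scikit-learn's `RandomForestClassifier` (seeded, single-threaded); the
Gini computations and an exhaustive midpoint-threshold split search are
implemented and tested independently, and the fitted root splits are
checked against that exhaustive search.

## Evaluation protocol

Known interactions are positives; all unknown drug–protein pairs form the
negative universe. 20% of positives plus an equal number of sampled
negatives form an independent test set; the remaining positives are
partitioned into 5 folds, each validated against an equal number of
negatives sampled once per plan (fixed, not resampled per fold, for
reproducibility). Training negatives are drawn 1:1 with training
positives, excluding every held-out negative of that fold. Metrics:
ROC-AUC (Mann–Whitney, ties ½), PR-AUC (precision–recall step-curve area
by descending-score sweep), and F1/accuracy/recall at threshold 0.5. The
per-fold mean is the headline number; the optimistically-biased best fold
is available separately. The ablation entry point evaluates each
(encoding × layer plan) cell on the shared independent test split by
default (`mode="cv"` runs the full per-cell cross-validation instead).

## Synthetic data

The generator plants `c` clusters (default 4) over `v = 60` drugs and
`m = 80` proteins. Each cluster owns a drug scaffold — 6–12 SMILES
fragments drawn from a concatenation-safe unit alphabet
{C, O, N, CC, benzene, C=C, CS, C(=O)} with two signature units per
cluster weighted ~10× above base, so clusters are chemically distinct —
and a protein signature: a 30-residue motif with cluster-specific 40- and
50-residue flanks (total length 120). Members are copies point-mutated at
rate 0.1 per unit/residue. Interactions are Bernoulli draws: probability
0.5 within a cluster, 0.02 across. All SMILES are validated through RDKit;
generation is deterministic in the seed and cluster labels are emitted for
independent verification.

What this emulates: datasets where string similarity is genuinely
informative about interaction structure, at a scale where every stage runs
in seconds. What it does not emulate: real chemistry (scaffold grammar,
not a compound library), real sequence statistics (uniform residue
background), hub drugs/promiscuous targets, or the sparsity of real
interactomes (~1–10⁻³ density vs. ~0.14 here). Passing the planted-signal
tests therefore demonstrates that the pipeline recovers cluster-structured
interaction signal from string similarity — not that it attains any
particular accuracy on real DTI data.

## Numerical choices and degenerate inputs

* Score-matrix cells floor at zero (local alignment); empty sequences are
  rejected.
* Degenerate similarity rows (max = min) become 0 off-diagonal with a
  warning; zero-norm drug vectors are an error naming the drug.
* Cosines are clipped to [0, 1]; symmetrization averages `(S + S^T)/2`
  then forces the unit diagonal.
* Attention softmax subtracts the row maximum before exponentiation;
  masked-out entries are exactly zero and receive no gradient.
* Forest split ties break toward the lowest feature index, then the lowest
  threshold (in the exhaustive reference; the sklearn backend resolves
  ties by its seeded randomized search, which is why split checks compare
  achieved impurity rather than chosen coordinates).
* Cross-entropy probabilities are clamped away from 0/1 by 10⁻¹²;
  a non-finite loss aborts training with the epoch index.
* Single-class training sets are rejected everywhere (encoder, forest,
  metrics requiring both classes).

## Known limitations

* The SELFIES codec is a subset implementation: it is exact on the neutral
  organic molecules it accepts, and refuses the rest; it does not aim to
  decode arbitrary mutated SELFIES strings the way the full grammar can.
* The encoder trains on the full dense graph; cost grows as O((v+m)²·d)
  per epoch, fine for hundreds of nodes, unsuitable for tens of thousands.
* Dense similarity blocks make deep stacks over-smooth: much of the
  planted signal lives in the raw similarity rows, and the two-layer plan
  is occasionally on par with the default three-layer plan at these sizes.
* Best-of-folds reporting is optimistically biased and deliberately not
  the headline; the repeated-test-averaging variant of independent testing
  is not implemented.
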