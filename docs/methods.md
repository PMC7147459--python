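# Methods

## Problem

Drug–target binding affinity (DTA) regression predicts a continuous
interaction strength — a pKd value or a KIBA composite score — for a
(compound, protein) pair, rather than a binary interacts/does-not-interact
label. `wfdta` implements a DTA predictor whose two inputs are a
word-frequency-weighted peptide-composition vector for the protein and a
molecular graph for the drug, fused by a hybrid graph-network /
1D-convolution regressor, together with the evaluation metrics and a
random-forest variable-importance analysis of the protein features.

## Protein encoding

Sequences are drawn from a 25-letter alphabet: the 20 standard residues
plus the extended codes B, O, U, X, Z (uppercase A–Z without J, in
lexicographic order). The alphabet identity is configurable; this default
covers the extended one-letter codes that occur in public kinase sequence
sets. An n-peptide maps to a vector index by base-25 positional encoding,
first letter most significant, giving feature widths 25, 625 and 15,625
for n = 1, 2, 3.

For a sequence of length L, the polypeptide-frequency vector is

    v_i = n_i / (L − n + 1),

the count of windows matching peptide i over the number of n-mer windows,
so each vector sums to 1. We use the window count L − n + 1 as the
denominator at every order; for dipeptides this equals L − 1. A
`strict_denominator` flag forces L − 1 at all orders for compatibility
with formulations written only for the dipeptide case, at the cost of
vectors that no longer sum to 1 when n ≠ 2.

The word-frequency (WF) encoding multiplies each within-sequence frequency
by the fraction of corpus sequences containing that peptide:

    wf_i = (w_i / N) · p_i / (L − n + 1).

This damps rare peptides instead of boosting them — the opposite of the
IDF weight log10(N / w_i), which the package computes only for comparison
(entries with w_i = 0 are reported as NaN, not 0). WF weights are fitted
on the training corpus only and reused unchanged for held-out sequences;
fitting them on all data would leak test-set composition into the encoder.

## Drug graphs

RDKit parses each SMILES; every heavy atom becomes a node with a 78-dim
one-hot feature vector: element symbol (43 named elements + catch-all, 44
slots), atomic rank (11 slots, 0–10), total hydrogen count (11), implicit
valence (11), and an aromaticity bit. "Atomic rank" is, by default, the
number of bonds to neighbouring heavy atoms plus the number of attached
hydrogens; a `rank_mode="degree"` option uses the heavy-neighbour degree
alone, the more common convention. Both give 78-dim features, so
downstream layer shapes are unaffected. Counts above 10 are clamped into
the top bucket with a warning. Each chemical bond contributes a directed
edge in both orientations; hydrogens are implicit, and bond orders,
chirality and 3D geometry are deliberately not featurized — the graph
carries connectivity only.

## Network architectures

Four drug-branch kinds embed the molecular graph into 128 dimensions:

* **gcn** — three graph-convolution + ReLU units with output channels
  78, 156, 312 (symmetrically normalized adjacency with self-loops),
  global max pooling, a 1024-unit dense layer with dropout, 128-dim out.
* **gin** — five graph-isomorphism units, each a two-layer 32-wide MLP over
  the summed neighbourhood, global sum pooling, 128-dim out.
* **gat** — additive-attention layers of 78 channels × 10 heads then 128
  channels × 1 head (self-loops added so single-atom graphs stay defined),
  global max pooling, 128-dim out.
* **gat_gcn** — a 78-channel 10-head attention layer into a 780-channel
  graph convolution, concatenated max + mean pooling (1560), a 1500-unit
  dense layer with dropout, 128-dim out.

The protein branch is a single-channel 1D convolution over the WF vector
(default 32 filters of kernel width 8 — "kernel size 32" is ambiguous
between filter count and width, so both are configurable), ReLU, flatten,
and a dense map to a 128-dim embedding matching the drug branch. A
`protein_embed_dim=256` flag reproduces the wider protein-head variant, in
which the fused vector is 384 wide instead of 256. The fused embedding
passes through dense layers of 512 and 128 units (ReLU, dropout 0.2) to a
single linear output.

Pooling choices (max for gcn/gat, sum for gin, max+mean for gat_gcn)
follow the established usage of each layer family. Activations are ReLU
throughout; there is no batch normalization.

## Training

The networks are built on a compact reverse-mode automatic-differentiation
engine (`wfdta.nn`) over NumPy float64 arrays: dense/sparse matrix
products, broadcasted arithmetic, ReLU-family activations, row
gather/scatter, segment reductions and segment softmax — the closed set of
operations these architectures need. Graphs are batched block-diagonally.
Everything is seeded and deterministic: the same config and data give
bit-identical parameters and loss curves.

Training minimizes MSE with Adam. Labels are z-scored on the training set
inside the trainer and restored to original units at prediction time, so
optimization behaves identically for pKd-scale (~5–10) and KIBA-scale
(~10–15) labels; reported history values are in original units.
Reference defaults follow the large-benchmark setting (batch 512, learning
rate 5e-5). The desk-scale synthetic runs in the tests and the acceptance
script instead use batch 32, learning rate 1e-3 and 30 epochs — a few
hundred Adam steps sized to a 160-pair training set, where the reference
setting would make less than one gradient step per epoch. Non-finite
losses abort with a diagnostic rather than training through NaNs.

## Evaluation metrics

The concordance index counts, over all pairs with strictly larger true
affinity, whether the prediction order agrees (ties in predictions score
0.5); pairs with tied truths are excluded from the normalizer. MSE is the
plain mean of squared errors. Pearson correlation is cov(p, y)/(σ(p)σ(y))
with a single (population) variance convention — the ratio is
convention-invariant. The vectorized CI is verified in the tests against
an independent O(n²) pair-enumeration oracle.

## Variable importance

`compute_vim` fits a seeded scikit-learn `RandomForestRegressor`
(reference default 10,000 trees; tests use 500) on the encoded protein
features against the affinities and reports mean-impurity-decrease
importances normalized to sum to 1, labelled by peptide string.
Permutation importance is available behind a flag, with negative values
clipped to zero before normalization. `rank_features` filters at a
contribution threshold (default 0.5%) and the report carries the count of
non-zero importances; dipeptide reports can be laid out as a 25×25
first-residue × second-residue grid.

## Synthetic benchmark generator

The generator emulates the dense proteins × drugs structure of
kinase-panel affinity benchmarks at desk scale. Proteins are i.i.d.
uniform over the 25-letter alphabet with lengths uniform in 200–400
(typical kinase-domain scale); drugs are drawn from ten drug-like
scaffolds (benzene, indole, piperidine, morpholine, benzamide,
sulfonamide, pyrimidine, benzothiazole, biphenyl, anilide) with a randomly
chosen substituent grafted at a marked position, every product validated
by the SMILES parser. Affinities follow a planted linear model

    y(d, p) = β0 + β_pep · v_PE(p) + β_size · heavyatoms(d) + ε,

with defaults β0 = 5 (a mid-range pKd baseline), planted dipeptide "PE",
β_pep = 200, β_size = 0.05 and ε ~ N(0, 0.3²). The planted-dipeptide
frequency of a random 200–400-residue sequence is 0 or a few multiples of
1/(L−1) (~3–10 × 10⁻³), so β_pep = 200 makes the protein term's spread
(≈0.6–0.8) clearly exceed the noise; β_size contributes ≈0.3 spread over
10–30 heavy atoms. Signal is planted on both the protein side (a
dipeptide) and the drug side (molecular size) so both network branches and
the variable-importance analysis have recoverable structure. All
randomness flows from one spec seed through named substreams (proteins,
drugs, noise).

What the generator does **not** emulate: real kinase sequence composition
and homology structure, realistic chemistry–affinity relationships, KIBA
score semantics, assay noise heterogeneity, or missing cells. Passing
tests therefore demonstrate that the pipeline recovers a known planted
signal under controlled conditions — not that the architecture reaches any
particular accuracy on real kinase benchmarks.

## Problem sizes and numerical choices

Smoke training uses a 20-protein × 10-drug cross product (200 pairs, 160
train) for 30 epochs per branch; variable-importance recovery uses 20
replicates of a 30 × 10 benchmark (300 rows, 625 features) with 500 trees.
These sizes are the package's chosen desk-scale study conditions: large
enough for the planted signal to dominate, small enough to run in minutes
on one CPU. Dataset splitting is uniform over (drug, protein) pairs
(warm start); cold-start splits by unseen drug or protein are out of
scope. Ties in `segment_max` pooling route the gradient to the first row
attaining the maximum; dropout masks come from a dedicated seeded stream;
the interaction-count filter iterates to a fixpoint by default (a
single-pass mode exists behind a flag).

## Known limitations

* Full-scale training on the real Davis/KIBA downloads (long stochastic
  training, external data) is out of scope; the package ships no real
  benchmark data.
* The NumPy engine is single-threaded and sized for desk-scale problems;
  it is not a platform for GPU-scale replication.
* n = 3 encodings (15,625 features) make the protein dense layer large;
  they work but are slow, and the dipeptide order n = 2 is the default.
* KIBA scores are used untransformed; only Kd values in nM are converted
  (pKd = −log10(Kd/10⁹)).
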