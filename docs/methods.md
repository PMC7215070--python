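# Methods

`ppistack` predicts whether two proteins physically interact from their
amino-acid sequences alone.  It combines four classical sequence
representations, a pair classifier built from convolution and multi-head
cross-attention, and stacked generalization over a grid of such classifiers.
This note records the model, its assumptions, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Sequence representations

Every protein is mapped to fixed-length vectors under four techniques.  All
four are pure functions of the sequence string.

**Autocovariance (AC, 210 values).**  Seven physicochemical scales per
residue — hydrophobicity, hydrophilicity, side-chain volume, polarity,
polarizability, solvent-accessible surface area, net charge index — are
standardized to zero mean and unit variance over the 20 amino acids, then
for each property j and lag `lag` in 1..30:

    AC(lag, j) = (1 / (L - lag)) * sum_i (X[i,j] - mean_j) (X[i+lag,j] - mean_j)

with `mean_j` the full-sequence property mean.  Ordering is lag-major.
Standardization makes the encoding invariant to the affine scale of the
published property tables; centering makes it invariant to adding a constant
to any column (asserted in tests).  The numeric scales are the ones
conventionally used with this encoder; they are versioned in
`properties.py` with per-column provenance comments.

**Conjoint triad (CT, 343 values).**  The 20 amino acids collapse to 7
groups by dipole moment and side-chain volume (A/G/V; C; F/I/L/P; M/S/T/Y;
H/N/Q/W; K/R; D/E).  Every window of three consecutive residues is a triad
over {1..7}^3; the vector holds each triad's count among the L-2 windows
divided by L-2, indexed lexicographically.  Boundary pseudo-triads (windows
extending past either end) have no bin among the 343 types and are not
counted.

**Local descriptor (LD, 630 values).**  Ten overlapping regions — four
quarters, two halves, central 50%, first/final/central 75%, all with
floor-based half-open cut points — each yield 63 statistics over the 7-group
alphabet: composition (7 group fractions), transition (21 unordered
group-pair adjacency frequencies over the n-1 adjacent positions) and
distribution (per group, five quantile statistics).  The distribution
statistic follows count-index arithmetic: 1/n, then floor(q*c + 0.5)/n for
q in {0.25, 0.5, 0.75, 1.0} with c the group count.  A `positional` variant
(position of the residue at each occurrence quantile, divided by n) is
available via `ld_ctd(..., distribution="positional")`; the count-index form
is the default because it reproduces the published worked arithmetic this
package is tested against.  With 7 + 21 + 35 = 63 values per region the full
vector is 630-dimensional.

**Pseudo-amino-acid composition (PseAAC, 20 + lambda values).**  The 20
residue frequencies f_k are extended by lambda sequence-order terms
theta_j, each averaging an order-relationship J over residue pairs j apart;
J is the mean plain difference of three standardized properties
(hydrophobicity, hydrophilicity, side-chain mass).  The whole vector is
divided by sum(f) + omega * sum(theta), omega = 0.05, so it sums to one.
Default lambda = 15.  Canonical PseAAC uses a squared difference in J; the
plain difference is the default here (it is what the formula this package
implements states), with `correlation="squared"` as a switch.  Note the
plain-difference form permits negative theta.

**Non-standard residues.**  The default `impute` policy maps B/Z/U to their
dominant resolutions (acid group / acid group / cysteine group) and to
property-column means (zero after standardization); X/J/O are dropped from
group strings with a warning.  A `strict` policy raises, naming the
position.

## The basic learner

A pair (P1, P2) arrives as two feature vectors reshaped to (positions x
channels) sequences: AC (30 x 7), CT (49 x 7), LD (90 x 7), PseAAC
((20+lambda) x 1); concatenated inputs use 7 channels.  The classifier is:

1. **Shared convolution stack** — n_blocks of Conv -> BatchNorm -> ReLU,
   then a closing Conv ('same' padding, odd kernel, default one block,
   kernel 3), giving per-position embeddings S1, S2 with d_model channels.
2. **Cross-attention with pooling** — S1' = pooledMultiHead(S1, S2, S1) and
   symmetrically S2'.  MultiHead is the standard h-head scaled dot-product
   attention with learned projections and output projection.  The pooling
   step forms the bilinear channel map G = M^T Q / P (M the attended
   output, Q the query input, P positions) and concatenates average and max
   pooling of G along its last axis, giving a 2*d_model vector whose length
   is independent of the sequence length.  The published formula for this
   step is dimensionally ambiguous (a matrix product of M with Q admits
   several orientations); this orientation is the one consistent with the
   stated requirement that the output be a fixed-length vector independent
   of input length, and in ablations the alternative (positions x positions
   map) memorized the training pairs without generalizing.
3. **Merge layer** — concat(cos(S1', S2'), S1'^T A S2', S1', S2') with a
   learned square matrix A; the cosine of a zero-norm vector is defined as
   0 (implemented with a 1e-12 additive guard).
4. **Dense head** — ReLU layers (grid: (128,64), (256,128), (128,64,32),
   (256,128,64)) and a 2-unit softmax.

The similarity term of the merge layer also admits an element-wise reading
(the normalized product kept per coordinate); it is available via
`merge_similarity="elementwise"` and performed indistinguishably from the
scalar cosine in A/B runs, so the scalar remains the default.

Training minimizes cross-entropy with Adam (default 1e-3) in float32.
Inputs are standardized per feature on the training set and winsorized at
±3 standard deviations.  Because an interaction is a property of the
unordered pair, each training pair is presented in both slot orders, and
prediction averages the two orders.  A seeded 10% validation split drives
early stopping (patience on validation loss, best-epoch weights restored).
All randomness flows from the config seed; two runs with the same seed are
bit-identical.

The learner and meta-learner run on a compact reverse-mode autodiff core
(`ppistack.autograd`) written on numpy; its gradients are verified against
central finite differences in the test suite.  ReLU and max-pool kinks and
the batch-norm-cancelled conv-bias direction are the expected (and
tolerated) finite-difference discrepancies.

## Stacked generalization

Sixteen learners (4 encodings x 4 dense/head settings, heads h in {2, 4})
form the first layer.  Model width is 32 for the conjoint-triad and
local-descriptor learners; the autocovariance and PseAAC learners, which
carry less pair signal and plateau early on this task, run at width 16 with
a shorter epoch budget.  Under stratified K-fold
cross-validation (K = 5), each learner is trained K times on fold
complements; sample i's meta-feature for learner m is the positive-class
probability from the one fold-model that did not see i.  This out-of-fold
guarantee is the load-bearing property of stacking — it is asserted
directly by an audit over fold indices in the tests.  Test-time
meta-features average the K fold-models.  The meta feature per learner is
the scalar positive-class probability (the 2-vector softmax is redundant).

The second layer is a small feed-forward network (hidden widths 32, 16,
ReLU, softmax output) trained by full-batch gradient descent with rate eta
= 0.05 until the gradient max-norm drops below epsilon = 1e-4 or 600
iterations.  Labels are used only as targets, never as meta-features.

Variants: `full` (the 4x4 grid), `concat` (learners on the single
concatenated 1183+lambda vector) and `single:<tech>` (one encoding's
4-config column).

## Dataset construction rules

Positives are cleaned by a length filter (drop pairs containing a protein
under 50 residues) and an optional global-identity redundancy filter
(Needleman–Wunsch identity = matches / alignment length, greedy first-seen
representative retention, threshold 0.40).  The identity filter is off by
default: the redundancy tool behind the published threshold is unnamed, and
the synthetic benchmark has no homology structure to remove.

Negatives pair proteins with differing subcellular localizations, at ratio
1:1 to the positives, excluding any pair present in the positive set, with
a per-protein occurrence cap (default ceil(2 * n_neg / n_proteins)) as the
operationalization of balanced per-protein contribution.  The cap is a
preference, not a constraint: when the default cap cannot reach the
requested count, it relaxes by one and continues.  Sampling enumerates
eligible pairs and draws with a seeded generator, so it is exactly
reproducible.  Pairs are stored unordered (lexicographically smaller id
first) everywhere.

## The synthetic benchmark

The generator emulates the shape of a curated PPI dataset: ~300 proteins of
60-400 residues with i.i.d. background residues at Swiss-Prot-like
frequencies, seven localization classes assigned independently of sequence,
and a planted interaction rule.  Four 30-residue motif families form two
complementary couples (2f binds 2f+1); 45% of proteins carry one family's
motif, inserted at a random position with 5% per-position divergence.
Positive pairs are sampled among complementary carriers (500 by default);
negatives come from the localization rule above.

Design rationale, fixed once before the acceptance runs: carriage is sparse
because in real proteomes only a minority of protein pairs share a binding
interface — dense carriage makes the cross-localization negative pool
heavily contaminated with true complementary pairs (measured up to 36% of
negatives in a dense draft, capping even an oracle's achievable AUC near
0.8).  Under the sparse defaults the measured contamination is ~2% of
negatives and a plain logistic probe on symmetrized CT pair features
reaches AUC ≈ 0.86, establishing that the label is learnable from sequence.
Localization is drawn independently of the motif families so that
localization-based negative sampling stays non-circular: the only
sequence-borne signal is the motifs.

What passing on this benchmark does NOT show: the generator has no homology
families, no length/composition biases correlated with interaction, no
localization signal in the sequence, and motif presence is binary rather
than affinity-graded.  Real PPI data violate all four, so synthetic
performance bounds nothing about real-data performance; the benchmark
establishes only that every pipeline stage is wired correctly and that the
architecture can recover a sequence-encoded pairwise signal at this sample
size.

## Problem sizes and runtime choices

The default end-to-end run trains 16 x 5 = 80 basic learners on 800
training pairs (a stratified 80/20 split of the 1000) with up to 40 epochs
each under early stopping, then the meta-network — minutes on one CPU in
float32.  The label-permutation control, which only needs to demonstrate
collapse to chance, uses the `single:ct` 4-learner column.  These sizes are
the package's desk-scale defaults; larger runs only change the config.

## Known limitations

* Pipeline stage caching is file-existence based plus a recorded config
  hash; editing a config between runs without clearing the run directory
  can serve stale caches.
* The identity filter is O(n^2) global alignments — fine for hundreds of
  proteins, not for proteomes.
* The autodiff core implements exactly the operations this architecture
  needs; it is not a general-purpose framework.
* Single-learner AUCs on the synthetic benchmark vary by a few points
  across seeds; conclusions should rest on the stacked ensemble, which is
  the method's endpoint.
* At the desk-scale conditions (800 training pairs) the stacked ensemble's
  held-out AUC sits around 0.80-0.86 depending on the run seed — well above
  chance and the single-technique learners' typical level, but short of the
  ~0.97 ceiling that a contamination analysis and a gradient-boosting probe
  show the data supports.  The architecture's pair representation, not the
  data, is the binding constraint at this sample size; larger pair sets
  narrow the gap.
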