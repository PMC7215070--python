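# Default pipeline configuration (documented schema).
# Any key may be omitted; these values are the defaults.

seed: 0

# Data source A: the synthetic benchmark (planted motif-complementarity rule).
simulate:
  n_proteins: 300
  length_range: [60, 400]     # residues; minimum stays clear of the length filter
  n_motif_families: 4         # two complementary couples
  motif_length: 30            # domain-scale binding motif
  insertion_noise: 0.05       # per-position divergence on insertion
  motif_prob: 0.45            # fraction of proteins carrying a motif
  max_families: 1             # families per carrier protein
  n_positive_pairs: 500
  localization_count: 7

# Data source B: real files (set `simulate: null` and fill these paths).
inputs: null
# inputs:
#   fasta: proteins.fasta
#   pairs: positive_pairs.tsv        # TSV: idA, idB, label
#   localization: localization.tsv   # TSV: id, localization

filter:
  min_len: 50            # drop pairs containing a protein shorter than this
  max_identity: null     # optional redundancy filter, e.g. 0.4; null = off
  neg_ratio: 1.0         # negatives per positive (1:1 class balance)

encoders:
  lag: 30                       # AC maximum lag (vector length 7 * lag)
  lambda: 15                    # PseAAC sequence-order depth (length 20 + lambda)
  ld_distribution: paper        # 'paper' (count-index) or 'positional'
  pseaac_correlation: paper     # 'paper' (plain difference) or 'squared'

split:
  test_fraction: 0.2     # stratified held-out fraction

ensemble:
  variant: full          # 'full' (4x4 grid), 'concat', or 'single:<tech>'
  folds: 5
  epochs: 40             # per basic learner (early stopping may end sooner)
  channels: null         # model width override; null = per-config grid width
  n_blocks: 1            # Conv->BatchNorm->ReLU repetitions before final conv
  meta_layers: [32, 16]  # hidden widths of the second-level network
  eta: 0.05              # meta-learner gradient-descent rate
  max_iters: 600         # meta-learner iteration cap
  epsilon: 1.0e-4        # stop when gradient max-norm falls below this
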