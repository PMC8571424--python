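# Methods

## Problem and model

The package predicts whether a protein sequence belongs to the
stress-response class (heat shock proteins, chaperones, disulfide
isomerases, ...) from sequence alone. Variable-length sequences are mapped
to a fixed 150-value descriptor combining three views of the primary
structure — local order (moments of a 2-D layout), relative residue
positioning (PRIM/RPRIM moments), and composition with absolute
positioning (frequency vector, AAPIV, RAAPIV) — and standard binary
classifiers are trained on the descriptors. The modelling assumption is
that class membership is detectable from composition and residue
arrangement statistics; no homology, structure, or annotation information
is used.

## Encoding and the two alphabets

Residues are encoded through a fixed 23-symbol table
(X,A,C,D,E,F,G,H,I,K,L,M,N,O,P,Q,R,S,T,U,V,W,Y → 0..22). X is the
catch-all unknown symbol; ambiguity codes (B, J, Z) and any other letter
are mapped to X's code 0. This normalization is a package convention: how
such letters were treated upstream in curated data sets is generally
unstated, and folding them into the unknown symbol is the conservative
choice. The rare residues O and U carry their own codes in the 2-D moment
representation but are excluded — together with X — from every 20-length
vector and 20×20 matrix, which index the standard amino acids
alphabetically (A..Y).

## Moment computation

A length-L code sequence fills an N×N grid row-major, N = ⌈√L⌉, with the
tail zero-padded (0 = the code of X, so padding is "unknown residue", not
signal). Conventions that silently change values and are therefore fixed
here explicitly:

- Raw and central sums use **1-based** grid indices; Hahn sums use the
  **0-based** support x = 0..N−1, the standard convention for discrete
  orthogonal polynomials.
- The ten (x, y) orders are taken in the fixed order
  (0,0),(1,0),(2,0),(3,0),(0,1),(1,1),(2,1),(0,2),(1,2),(0,3) within each
  family, and families are concatenated raw + central + Hahn.
- If the grid mass G00 is zero (an all-X sequence) the centroid is
  undefined and all central moments are defined as 0.
- Hahn shape parameters are both 0 — the simplest member of the family,
  for which the polynomials coincide with the discrete Chebyshev (Gram)
  family. Orthonormality, the only property the construction relies on,
  holds for any admissible choice. The basis is built by the three-term
  recurrence (k+1)t_{k+1} = (2k+1)(2x−N+1)t_k − k(N²−k²)t_{k−1} and each
  vector normalized numerically; for order ≥ N the basis is exhausted and
  the zero vector is used. The Gram matrix is the identity to 1e−9 for
  all tested N ≤ 64.
- Everything is computed in double precision with no overflow guard:
  for sequence lengths up to ~10⁴ the largest term l³·β stays far below
  the double range.

## PRIM / RPRIM

M_{i→j} sums the offsets of **all** occurrences of amino acid j relative
to the **first** occurrence of amino acid i; occurrences preceding it
contribute negative offsets, and rows for absent amino acids are zero.
The signed-inclusive reading is adopted because it is the literal reading
of "positions relative to the first occurrence" and keeps the matrix
integer-valued; excluding or taking absolute values of preceding
occurrences are defensible alternatives that produce different (also
integer) matrices, so the choice is versioned here. The 20×20 matrices
are fed to the moment engine directly — they already satisfy the
square-input requirement, and the moment sums accept negative entries.

## Feature vector

Block order is seq-moments(30) | PRIM-moments(30) | RPRIM-moments(30) |
frequency(20) | AAPIV(20) | RAAPIV(20). The order is arbitrary but
load-bearing: a trained model is only valid for the exact order it was
trained with, so a fingerprint (SHA-256 of the ordered feature names) is
stored in every model file and checked at prediction time.

## Classifiers

- **Random forest:** 50 trees, otherwise library defaults. Scale-invariant,
  so no standardization by default.
- **Neural network:** one hidden layer of 50 ReLU units over the 150
  inputs, trained by SGD back-propagation at learning rate 0.001 with a
  fixed budget of epochs (default 100, batch 32). Realised with
  scikit-learn's MLPClassifier; its single logistic output for binary
  problems is decision-equivalent to a two-unit one-hot sigmoid head.
  Plain SGD (not an adaptive optimizer) is the default because the
  training procedure is described only as gradient descent; the optimizer
  is configurable.
- **Linear SVM:** libsvm-backed linear kernel at the default margin
  penalty C = 1.
- Raw moments span many orders of magnitude (G00 ~ 10²–10³, G30 ~ 10⁶–10⁸
  for typical lengths), so per-feature standardization — fitted on
  training rows only — defaults to **on** for the scale-sensitive neural
  net and SVM and **off** for the forest. The setting is recorded in the
  model file so every evaluation is attributable.

## Validation protocols and metrics

Sn, Sp and Acc are reported in percent; MCC in [−1, 1]; AUC by the
trapezoid rule over thresholds at every unique score. Any metric with a
zero denominator is defined as 0. Reported values are rounded
half-away-from-zero to one decimal (percentages) or two (MCC); unrounded
values are preserved in the report JSON.

- *Self-consistency*: resubstitution (train = test). An interpolating
  forest scores ≈100% here by construction; the protocol measures model
  capacity, not generalization.
- *Jackknife*: leave-one-out with re-initialization each iteration; the
  per-iteration confusion cells are **pooled** (n accuracies of 0/1 are
  meaningless individually). Training-row order is canonicalized
  (lexicographic sort of feature rows) before each fit so the pooled
  result is a function of the sample set only — bootstrap and mini-batch
  sampling otherwise make row order leak into the fit, breaking the
  protocol's defining property of a unique output per dataset.
- *Independent split*: stratified 70/30 with an integer test size
  round(0.3·n).
- *k-fold* (k = 5, 10): seeded stratified partition; headline numbers are
  the mean of per-fold metrics, and per-fold values are kept in the
  report for dispersion summaries. Stratification (within ±1 sample per
  class per fold) is a package choice that prevents degenerate
  single-class folds at small n.

## Synthetic data generator

The generator emulates a curated two-class protein set at desk scale:
uniform lengths on a configurable range (default 50–150 residues, grids
8×8–13×13), residues drawn i.i.d. from per-class composition vectors over
the 20 standard amino acids, an optional motif planted in one class
within a position band, and a residue-randomization noise rate.

- The **null preset** uses identical class distributions with full
  randomization: any cross-validated accuracy significantly off 50%
  indicates leakage in the pipeline.
- The **strong preset** doubles A and K frequency in the positive class
  and plants a 12-residue motif of rare-in-background residues
  (WYWHCYHWCYWH) in the first fifth of the sequence. Twelve residues is
  the scale of a short conserved domain; a much shorter motif contributes
  too little through the 30 moment features to qualify as a strong
  positional signal, leaving the composition shift as the only usable
  cue. With this preset a 50-tree forest reaches ≥90% five-fold accuracy
  at n = 100 + 100, with signal recoverable from both the composition and
  the positional blocks (so ablations can attribute skill to blocks).

What the generator does **not** emulate: realistic amino-acid background
composition, homology/redundancy structure, domain architecture, or
length–class correlations of real curated data. Passing pipeline tests on
synthetic data therefore demonstrates that the machinery is correct and
that known signal of each kind is recoverable — not that any particular
real-data accuracy will be attained.

## Problem sizes

Default test and reproduction runs use 200-sequence datasets (100 per
class) for signal recovery, 5 × 120 sequences for the null control, and
200 random sequences for brute-force oracle comparisons — sizes at which
every stage's behaviour is already stable and the whole suite runs in
well under a minute.

## Known limitations

- The PRIM offset convention (see above) is one of several defensible
  readings; matrices are not comparable across conventions.
- MCC of a confusion matrix is reported at its recomputed value; some
  published summaries truncate rather than round such values, so the last
  digit may differ from a truncated source even when the cells agree.
- The SVM score used for ROC is a logistic squashing of the signed
  margin: monotone (hence ROC/AUC-correct) but not a calibrated
  probability.
- Feature extraction is O(L) per sequence with small constants, but the
  jackknife protocol refits the model n times and is intended for small
  n.
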