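# Methods

## Problem and model

A mitochondrial protein is classified into one of four sub-mitochondrial
compartments: outer membrane, inner membrane, intermembrane space, matrix
(fixed class order throughout; Gene Ontology terms GO:0005741, GO:0005743,
GO:0005758, GO:0005759). The classifier is a single-convolutional-layer
network with dual global pooling:

* **Input.** L×d per-residue feature matrix. Channel order within each
  descriptor block is alphabetical by one-letter residue code
  (A,C,D,…,Y). Non-canonical letters (X, B, Z, U, O, J) become all-zero
  rows in every descriptor: injecting no signal is safer than any
  imputation. The `PROP` block is the 10 Kidera factors, bundled verbatim
  from the published table (Kidera et al., J. Protein Chem. 4:23–55, 1985)
  without renormalization. The `PSSM` block is the first (log-odds)
  20-column block of a PSI-BLAST ASCII matrix — the last-iteration ASCII
  matrix, not the binary checkpoint — remapped from the file's A R N D …
  column order and squashed by the logistic sigmoid; log-odds near 0 map
  near 0.5, so the encoding is well-spread in (0,1), which percentage
  columns would not be.
* **Convolution.** F detectors of odd width w, zero-padded by ⌊w/2⌋ per
  side so the response keeps length L for every L ≥ 1 (sequences shorter
  than w are handled by the padding; L = 0 is rejected at the record
  level). A learnable bias per detector is included; it is standard
  practice, zero-initialized, and harmless. Activation ReLU.
* **Pooling.** Global mean and global max of each detector's response,
  concatenated (2F values). Mean captures distributed composition signal,
  max captures the best local motif match; together they make the
  representation length-invariant. A general local-pooling utility
  (non-overlapping blocks of p columns) is provided but not used by the
  classifier.
* **Classifier head.** One ReLU hidden layer (H units), then four
  independent sigmoid outputs. The hidden activation is a free choice in
  the formalism; ReLU is used. Prediction is the argmax score; exact ties
  go to the first class in the fixed order, for determinism.

## Training

Plain mini-batch SGD (no momentum) minimising the cumulative binary
cross-entropy: the sum over the four classes of the per-class binary
cross-entropy, averaged over the batch. Defaults: learning rate 0.01,
batch size 32, at most 100 epochs, early-stopping patience 10 — the
optimisation settings are not part of the architecture search and are
configurable. Output scores are clipped at ε = 1e−7 inside the loss only,
to keep logarithms finite; gradients use the exact sigmoid/cross-entropy
identity δ = (o − y)/N. Weights initialise uniform in ±√(1/fan_in) per
layer, biases zero, all draws from a generator seeded by the
hyperparameter seed; batch shuffling draws from the same stream, so a
(data, hyperparameters, seed) triple reproduces a model bitwise. Early
stopping tracks validation loss each epoch, keeps a copy of the best
weights, stops after `patience` consecutive non-improvements (strict
`<`), and restores the best epoch. An empty validation set degrades, with
a warning, to fixed-epoch training.

Model archives are zip files of raw `.npy` members plus a JSON header
(hyperparameters, class order, feature set, format version) written with
fixed timestamps, so identical models serialize to identical bytes.

## Model selection and cross-validation

Grid search over (F, w, H). The default grid is F ∈ {64, 128, 256},
w ∈ {7, 11, 15, 19}, H ∈ {64, 128, 256}; it is a stand-in chosen to
bracket, and contain, the reference optimum (256, 19, 256), since no
authoritative candidate list is available. Nested protocol: for test fold
t the validation fold is (t+1) mod k (an arbitrary but fixed rotation)
and the remaining k−2 folds train. Selection is by maximum validation
GCC; ties break toward fewer parameters, then enumeration order. The
winning combination's already-trained model scores the test fold — there
is no retraining on train+validation. Pooled test predictions over all
folds give one confusion matrix; every protein is predicted exactly once
by a model that never saw its fold.

## Homology-aware partitioning

Edges join proteins with at least one pairwise hit of identity strictly
greater than 30% (the wording "more than 30%" reads as strict) and
e-value ≤ 0.001 (a cutoff, read as inclusive; whether the e-value gates
edge creation or only the upstream search is ambiguous — it gates both
here). No coverage threshold. Self-hits are ignored; isolated proteins
stay as singleton clusters. Connected components implement single-linkage
clustering; output order is deterministic (size-descending, ties by
smallest id). Fold assignment is greedy: clusters in decreasing size
order each go to the currently smallest fold, ties among equally small
folds broken by a seeded draw — near-optimal balance with cluster
atomicity, hence exactly zero cross-fold similarity edges. Class
stratification is deliberately not enforced. A uniform random balanced
split (sizes differing by at most one) is provided for comparison
protocols.

## Scoring statistics

From the K×K confusion matrix M (rows true, columns predicted):

* **MCC_k** — one-vs-rest Matthews correlation from TP = M_kk,
  over-predictions o_k (column k off-diagonal), under-predictions u_k
  (row k off-diagonal) and true negatives n_k. Convention: 0 when any
  denominator factor vanishes (class absent from truth or predictions).
* **GCC** — √(χ²/(N(K−1))) with χ² the independence chi-square built from
  expected counts e_ij = a_i b_j/N. Cells with e_ij = 0 contribute 0.
  The square-root form is necessarily non-negative; prose descriptions of
  this statistic sometimes claim a −1…1 range, which the printed formula
  cannot produce — this implementation follows the formula. For K = 2 the
  value equals |MCC| exactly (verified exhaustively in the tests).
  Identical rows (predictions independent of truth) give exactly 0.
* **Q2mem** — among proteins truly in outer or inner membrane, the
  percentage predicted into either membrane compartment; swapping the two
  membranes still counts. Undefined (error) when the restriction is
  empty.

## Synthetic benchmark generator

The generator emulates the classifier's three inputs with controllable
signal:

* Sequences: lengths uniform on [50, 120] (typical of small
  single-domain mitochondrial proteins while keeping runtimes small),
  background residues uniform over the 20 canonical amino acids
  (configurable to natural frequencies), one distinct 8-mer motif per
  compartment planted at a random interior position. Each motif position
  is emitted verbatim with probability `motif_strength`: 1.0 plants it
  exactly; 0.0 severs any sequence–label dependence (the null model).
* Pseudo-profiles: integer log-odds noise (rounded N(0, 2), clipped to
  ±9) with the emitted residue at each motif position set to +5 — at
  strength 0 the "conserved" residues are background draws, so profiles
  carry no class signal either. Written in PSI-BLAST ASCII format, they
  round-trip bit-exactly through the parser.
* Redundancy: `n_duplicates` near-duplicate records (≈4% point mutations)
  are appended with >90%-identity hits, plus per-record self-hits and a
  scatter of sub-threshold (15–28% identity) background hits. Defaults:
  60 proteins per class, 5 duplicate pairs.

What this does *not* emulate: real compartment signals are distributed
(targeting peptides, transmembrane topology, composition biases), not
single verbatim motifs; real profiles encode family-wide conservation,
not one planted peak; and real redundancy forms larger, messier clusters.
Passing the learnability tests therefore demonstrates that the pipeline
learns and evaluates correctly, not that it attains any particular
accuracy on real proteomes — headline accuracies on curated datasets
require the original profiles and databases and are out of scope here.

## Numerical and design notes

* The sigmoid squashing is strictly within (0,1) for inputs |x| ≲ 36;
  beyond that float64 saturates to exactly 0/1. Profile log-odds are
  small integers, far inside the safe regime.
* Max-pool backpropagation routes the gradient to the first maximal
  column per detector (numpy argmax convention), a standard subgradient
  choice; ties have measure zero for continuous inputs.
* Parameter count: F(wd+1) + (2FH + H) + (HK + K); for the reference
  architecture (F=256, w=19, H=256, d=30, K=4) this is 278,532.
* Test and example problem sizes (tens of proteins per class, F ≤ 32)
  are chosen so the full suite runs in well under a minute of training
  per experiment on one CPU core; the implementation is O(F·w·d·L) per
  sequence and handles the reference architecture without modification.

## Known limitations

* No GPU path, momentum/Adam, or non-grid hyperparameter search — the
  intended scale does not need them.
* Multi-compartment (multi-label) proteins are out of scope; labels are
  single-compartment by construction.
* The CLI does not pre-screen for mitochondrial localization; inputs are
  assumed mitochondrial.
* Recurrent layers and local pooling variants are intentionally absent
  from the classifier.
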