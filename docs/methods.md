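# Methods

## Problem and pipeline

Sucrose transporters (SUTs) are identified from protein sequence by a
four-stage pipeline: curation of a FASTA set, per-protein feature
encoding, minority-class oversampling, and cross-validated
classification. The positive class (label 1) is the transporter; the
data regime of interest is roughly 1 : 2.4 imbalance (306 positives to
729 negatives in the training split, 76/182 in the holdout, after
80/20 stratified splitting of a 382/911 set).

## Curation

A sequence is kept iff it consists solely of the 20 canonical
one-letter codes and has length ≥ `min_length` (default 50). Ambiguity
codes (B, Z, J, X), the rare U/O and gap characters are treated as
illegal: every encoder indexes exactly 20 residue types, so a single
non-canonical character would leave descriptors undefined. Curation
returns a rejection list (`illegal_character` / `too_short`) rather
than raising, so a batch reports all bad records in one pass, and is
idempotent. Redundancy reduction (CD-HIT at 60% identity) is an
upstream step the pipeline assumes, not re-implements.

## Feature encoders

All encoders are pure functions emitting fixed, named schemas.

**188D.** Amino-acid frequencies F_i = N_i/L in alphabetical order
(20), then for each of 8 physicochemical properties — each a 3-group
partition of the alphabet — composition C_i = N_i/L (3), cross-group
transition frequencies T(i1,i2) = (N(i1,i2)+N(i2,i1))/(L−1) for the
unordered pairs (1,2), (2,3), (3,1) (3), and the distribution
descriptor (15): per group, the 1-based sequence positions of the
ceil(q·n)-th occurrence for q ∈ {first, 25, 50, 75, 100%} (n = number
of occurrences of that group), each divided by L. Choices made where
the convention is genuinely open:

- distribution values are reported as fractions of L in [0, 1] (not
  percentages), keeping features length-invariant;
- a group with zero occurrences contributes five zeros, keeping the
  vector dense and well defined;
- the quantile occurrence index is ceil(q·n) with the first-occurrence
  index forced to 1, making the five values non-decreasing.

Only the hydrophobicity partition (polar RKEDQN / neutral GASTPHY /
hydrophobic CVLIMFW) is canonical for this pipeline; the other seven
(normalized van der Waals volume, polarity, polarizability, charge,
secondary structure, solvent accessibility, surface tension) use the
standard three-state CTD tables and can be overridden from a YAML file
(`properties.load_groupings`) since published 188D implementations
vary in their group tables. Transition requires L ≥ 2 (denominator
L − 1) and raises otherwise.

**PSSM parsing.** The `-out_ascii_pssm` text format is parsed into an
L×20 matrix from the *log-odds* block (first 20 numeric columns), the
convention of the POSSUM descriptor suite; the weighted-percentage
block and per-position statistics are ignored. Column order is
asserted against the file's header letters, never assumed. Scores stay
raw (files carry integers); no sigmoid or other normalisation is
applied on the default path, because the descriptors below are defined
on the original profile. Profiles are matched to sequences by id via
the `pssm_dir/<id>.pssm` convention, with a strict mode (missing or
misaligned profile aborts) and a lenient mode (drop with warning).

**PSSM composition.** Rows of the profile are grouped by the residue
observed at each sequence position, summed per residue type and
divided by L; the 20 per-type 20-vectors are concatenated in PSI-BLAST
column order (400 values). Types absent from the sequence give zero
blocks.

**k-separated bigrams.** T[m,n](k) = Σ_{i=1..L−k} N[i,m]·N[i+k,n],
flattened row-major (400 values per k). k = 1 is the default headline
feature; `k_list` concatenates blocks for several separations (the
descriptor is defined for k up to 11). k ≥ L yields an all-zero block
with a logged warning (empty sum) rather than an error, so length
outliers do not abort a batch. The implementation is the matrix
product N[:−k]ᵀ N[k:], verified in the tests against a naive
triple-loop oracle.

Feature sets concatenate in the fixed order 188D, PSSM composition,
bigrams, giving widths 188 / 400 / 400 / 588 / 588 / 800 / 988 for the
seven non-empty combinations.

## Borderline-SMOTE (variant 1)

Each minority point p is classified by m′, the number of majority
points among its k = 5 nearest neighbours in the whole data set
(Euclidean on raw features, self excluded): m′ = k → noise,
k/2 ≤ m′ < k → danger, m′ < k/2 → safe. Only danger points are
oversampled: synthetic rows are p + r·(q − p) with q one of p's k
nearest *minority* neighbours and r ~ U[0, 1], generated until the
minority class exactly matches the majority count. Implementation
policies:

- the required count is distributed round-robin over the danger points
  in a seed-shuffled order, so no single point dominates;
- if no danger point exists (well-separated classes), parents fall
  back to all non-noise minority points — plain SMOTE behaviour — with
  a logged warning;
- distance ties break toward the lowest row index; k is clamped (with
  a warning) when it exceeds minority size − 1;
- features are *not* standardised before the distance computation by
  default (a flag enables it), matching common implementations; this
  is an assumption, as descriptor blocks have heterogeneous scales;
- original rows are never modified and precede all synthetic rows;
  synthetic ids carry a `synthetic|` prefix and every row's
  (p, q, r) triple is returned for audit, so interpolation can be
  verified exactly and leak checks can spot synthetic rows.

The whole procedure is deterministic given (data, k, seed).

## Evaluation

Metrics are computed once from confusion counts pooled over folds
(WEKA-style), not averaged per fold: SN = TP/(TP+FN),
SP = TN/(TN+FP), ACC, MCC with the square-root denominator,
PR = TP/(TP+FP), F = 2·SN·PR/(SN+PR). A zero denominator reports 0
and flags the metric by name rather than yielding NaN. ROC curves use
continuous scores (vote fraction for forests, decision function for
margin models) with trapezoidal AUC.

Folds are stratified (per-fold class counts within one of exact
proportionality) and seeded; stratification is an implementation
choice where the protocol is silent. Three balancing placements are
first-class and recorded in the report fingerprint:

- `per_fold` (default): the training portion of each fold is balanced;
  test folds never contain synthetic rows (asserted via id tags). This
  is the leak-safe protocol.
- `global_before_cv`: the whole set is balanced, then folded — the
  protocol of WEKA-era transporter studies. Synthetic neighbours of a
  training point can land in test folds, which optimistically biases
  the estimate; the mode exists for protocol reproduction and is
  labeled in reports.
- `none`.

Classifiers come from scikit-learn with library defaults unless
overridden: 100-tree random forest, linear-kernel SVC (an SMO-style
margin learner), Gaussian naive Bayes, and a hinge-loss SGD linear
model. The learners are deliberately not re-implemented; the
pipeline's contribution is curation, encoding and balancing, and the
exact hyperparameters enter the config fingerprint. The 80/20 holdout
split uses per-class floor(n·0.2) test counts, which reproduces the
76/182 holdout from 382/911 exactly (a global-rounding split would
give 76/183).

## Synthetic benchmarks

The generator emulates the shape of a curated transporter benchmark —
default 306/729 with lengths uniform on [50, 120] — with one signal
dial s ∈ [0, 1] injected through two independent channels so that
feature-ablation experiments are meaningful:

- residue composition: positives draw from
  (1−s)·uniform + s·bias over one half of the alphabet, negatives
  from the mirrored half (exercises 188D);
- profiles: integer noise uniform on [−3, 3], plus round(7s) on the
  true residue's column and round(2s) on two class-specific marker
  columns, clipped to [−10, 10] and written as valid ascii PSSM files
  (exercises the PSSM encoders). The true-residue boost dominates the
  marker boost so that at s = 1 the true column is the row maximum at
  ≥ 90% of positions while the markers still carry class signal.

At s = 0 the classes are identically distributed; discriminability is
monotone in s. The data are i.i.d. draws: no homology between samples,
no transmembrane motifs, no length–class correlation, and the
synthetic PSSMs are noise around a point signal rather than real
evolutionary profiles. Passing tests therefore demonstrate that the
pipeline machinery recovers planted signal and respects its
structural contracts — not that any particular accuracy is attainable
on real transporter data, which requires the curated UniProt/PFAM sets
and PSI-BLAST profiles against Uniref50.

Test problem sizes: the signal-recovery suite runs one high-signal
(s = 0.7) 306/729 bundle through the full chain and five zero-signal
replicates on 188D features; the balancing-direction experiment uses
s = 0.15, a moderate-overlap regime chosen because imbalance only
harms sensitivity when classes overlap near the boundary. These sizes
keep the default suite under two minutes while exercising the study's
class-count regime at full scale.

## Known limitations

- Euclidean distance on raw, unscaled descriptor blocks drives the
  oversampler; concatenated feature sets with heterogeneous scales may
  weight blocks unevenly (mitigation: `standardize=True`).
- Borderline-SMOTE2 (interpolation toward majority neighbours) is not
  implemented.
- The ascii-PSSM parser targets the `-out_ascii_pssm` layout only;
  binary checkpoints and other profile formats are out of scope, as is
  running PSI-BLAST itself.
- Model serialisation uses joblib; artifacts are tied to the installed
  scikit-learn version.
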