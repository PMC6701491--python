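# Methods

## Problem setting

The package classifies long non-coding RNAs (lncRNAs) as cancer-related
or not from a wide numeric feature table, with a confirmed-positive set
that is roughly thirty times smaller than the negative set, and then
subjects the ranked candidates to orthogonal statistical checks.  Three
methodological ingredients carry the work: unsupervised feature
selection (the labels are too few and too biased to select on),
over-sampling confined to training folds (the imbalance is severe, and
resampling before splitting would leak synthetic copies of validation
points into training), and a boosted-tree classifier with a fixed,
published hyperparameter set.

## Laplacian-score feature selection

**Model.**  Samples are nodes of a kNN graph (k = 5, Euclidean metric);
edge weights are heat-kernel, `W_ij = exp(−‖x_i − x_j‖² / t)`, with
union symmetrization (an edge exists if either endpoint ranks the other
among its k nearest).  For degree matrix `D` and Laplacian `L = D − W`,
a feature's score is the Rayleigh quotient `f̃ᵀLf̃ / f̃ᵀDf̃` after
degree-weighted centring.  Scores are non-negative and bounded by 2
(the spectral radius of the normalized Laplacian); low scores indicate
features that vary smoothly over the sample manifold.  The graph is
built on *all* rows — labelled and unknown — because the criterion is
unsupervised; a labelled-only graph is a caller option by subsetting.

**Standardization.**  Columns are centred and scaled to unit variance
before graph construction and scoring.  Euclidean distances across
heterogeneous omics units are meaningless otherwise, and the score
itself becomes scale-free (verified by a numerical invariance test).

**Bandwidth.**  The heat-kernel bandwidth defaults to the mean squared
kNN distance of the data rather than a fixed constant.  With p
standardized dimensions, typical squared neighbour distances grow like
2p; at p = 85 a fixed `t = 1` drives every weight below the smallest
positive double, leaving an empty graph.  Self-tuning keeps edge
weights in (0, 1] at any dimensionality and reproduces the fixed-`t`
behaviour exactly when a numeric value is configured.

**Gap partitioning.**  Per category, scores are sorted ascending and
consecutive differences ranked by magnitude (ties broken toward the
earlier, lower-score position; the tie-break is logged).  Two ranked
gaps — (1st, 2nd) by default, (2nd, 3rd) for the Epigenetic category,
whose spectrum's largest gap sits away from the visually meaningful
inflection — cut the spectrum into lower / middle / upper parts.
Categories with fewer than four finite-scored features are not split.
Constant features receive an infinite sentinel score and are parked in
the upper (least informative) part without entering the gap
computation.

**Mean-merge.**  Lower-part columns pass through verbatim.  The middle
and upper parts each collapse to their per-sample mean, named
`<Prefix>_LevelOne` and `<Prefix>_LevelTwo` and flagged `synthetic` in
the output metadata (the naming convention — LevelOne = middle,
LevelTwo = upper — is a package convention recorded in the metadata so
either reading can be audited).  An empty part emits no column.

## SMOTE

Synthetic minority rows are `x + u(x_nn − x)` with `u ~ U(0,1)`, `x` a
minority row drawn uniformly with replacement and `x_nn` one of its
k = 5 minority nearest neighbours.  The number generated is
`ceil(target_ratio · |majority|) − |minority|`, floored at zero; the
default target ratio of 1.0 (full balance) is the canonical SMOTE
objective — the original work tuned the amount but does not print it.
k is clamped to `|minority| − 1` with a warning when the minority class
is tiny.  Original rows pass through byte-identical, first, so a
boolean mask cleanly separates generated rows.

## Classification

The boosted ensemble is XGBoost with the binary logistic objective and
the published tuning: 546 estimators, depth 10, learning rate 0.01,
column subsample 0.7, row subsample 0.826, gamma 0.036.  Boosting
internals are delegated to the library; the wrapper pins the objective,
echoes the effective parameters, enforces a named-feature contract at
prediction time (columns are matched and reordered by name; any
difference is a hard error), and reports split-count ("weight") feature
importances.  Training defaults to one thread, which with the `hist`
tree method makes runs bit-reproducible for a fixed seed.  The final
model is trained on all labelled genes with the same SMOTE treatment as
the CV folds (a flag disables it).

## Cross-validation

Stratified 10-fold with shuffling; per-fold class counts deviate from
perfect proportion by at most one.  Per iteration the nine training
folds are over-sampled, a fresh model (seed = run seed + fold index) is
fitted, and the untouched validation fold is scored.  Because
resampling happens strictly inside the training partition, no synthetic
row can reach a validation fold; the test suite re-derives each fold's
resampling and asserts this byte-wise, along with the partition
property of the validation folds.  AUC is the Mann–Whitney statistic
with midrank tie handling, which equals the trapezoidal area under the
reported ROC points to machine precision.  Threshold metrics
(precision / recall / F1, per class and macro-averaged over the two
classes) are computed at a configurable probability cutoff, default
0.5; zero denominators yield 0 rather than NaN.

## Candidate ranking

Unknown genes are scored by the final model and sorted by probability
descending, ties broken lexicographically by gene ID so output is
deterministic.  `candidate` means probability strictly above the
threshold; a top-N view is also provided since both framings are in
common use.  Overlap between the unknown set and training IDs is a hard
error.

## Validation battery

* **Mutation burden** — mutations with `start ≤ pos < end` per gene
  body (0-based half-open); overlapping genes each count shared
  mutations.  Flanking regions are not counted.
* **Nearest cancer-gene distance** — same-chromosome gap between
  interval ends, 0 for overlap or abutment, strand-agnostic.  Queries
  with no same-chromosome target get an infinite sentinel and are
  excluded from KS comparisons with a logged count.  The background set
  is width-1 points placed uniformly, chromosome chosen proportional to
  length.
* **Differential expression** — per gene and tumour/normal pair,
  `log2((t+1)/(n+1))` (pseudo-count 1 guards zeros); a gene is DE when
  the *median* |log₂FC| across pairs exceeds 1.  Median aggregation is
  a deliberate resolution of an ambiguity (per-pair vs aggregate);
  an "any pair" mode is available and markedly more liberal.
* **KS test** — `D = sup |ECDF_a − ECDF_b|` evaluated over the pooled
  sample points; p-value from the limiting Kolmogorov distribution at
  effective size `nm/(n+m)`.  At the hundreds-of-genes scale used here
  the limiting distribution and finite-n refinements agree closely;
  note that on heavily tied discrete data (mutation counts) the KS
  p-value is conservative.

## Synthetic data

The generator's defaults are the study conditions: 150 positives, 4,500
negatives (1:30), 350 unknowns, 85 features split 18/16/27/24 across
the Genomic/Expression/Epigenetic/Network categories with the matching
column-name prefixes, a standardized mean shift of 1.5 planted on 10
informative columns (3/3/2/2 per category), and unit noise.  Each
category has a three-tier smoothness structure — 40 % of columns
strongly correlated (weight 0.95) with a two-dimensional latent sample
manifold, 25 % weakly correlated (0.6), the rest independent noise — so
the Laplacian-score spectrum shows three clusters separated by genuine
gaps and the partition stage has real structure to find.  Informative
columns live in the noise tier, keeping class signal and graph
smoothness independently plantable.  Six per cent of unknown genes
carry the positive signal: an unknown pool with no undiscovered
positives would make ranking vacuous, and real unknown pools are
exactly where new positives hide.

The genome fixture plants: positives placed an Exp(50 kb) gap from a
random cancer gene (negatives uniform), a 3× somatic-mutation rate
multiplier on positive gene bodies over a 6×10⁻⁴/bp background, and a
±2 log₂FC expression effect in 40 % of positives vs 20 % of negatives
with 0.25 log₂ per-pair noise — chosen so the DE fractions land near
the ~40 % / ~20 % regime reported for real positive and negative sets.
Every planted effect has a zero setting that produces an exchangeable
null, and the test suite checks both directions (effects detected at
planted strength; type-I error ≈ 5 % on null fixtures).

**What passing these tests does not show:** the generator draws
features from Gaussians with a linear latent structure and independent
informative columns; real omics features are heavy-tailed, collinear,
and batch-structured, and real negatives are themselves a biased
sample.  Near-perfect benchmark AUCs therefore validate the machinery
(no leakage, correct formulas, recoverable signal), not the real-data
performance level, which depends entirely on the real feature table.

## Numerical choices and degenerate inputs

* Constant features: sentinel score, upper part, warning.
* Zero-variance denominators in precision/recall/F1: 0 with warning.
* Tied gap magnitudes: earlier position wins, logged.
* Missing feature-table cells: hard error by default; opt-in column-mean
  imputation.
* All randomness flows through seeded NumPy generators; fold model
  seeds derive from the run seed plus the fold index, and the SMOTE
  stream per fold derives from `seed · 100003 + fold`.

## Problem sizes used in the shipped checks

The full benchmark (4,650 labelled genes, 546-tree ensemble, 10 folds)
is cross-validated twice (observed and permuted labels); the 20-seed
SMOTE/single-tree ablations run on a scaled 1:30 benchmark (25/750,
60 trees, depth 4, 5 folds), which preserves the imbalance and the
compared directions while keeping repeated runs cheap.  Type-I
calibration uses 200 null genome fixtures of 150 genes per set.

## Known limitations

* The probability cutoff that defines "candidate" is not identifiable
  from published information; 0.5 is a convention, and candidate counts
  should be read relative to a chosen threshold or top-N.
* KS p-values on discrete mutation counts are conservative; rank-based
  alternatives would be sharper but are out of scope.
* Distances are interval-gap based, not TSS-based, and strand is
  ignored throughout.
* No hyperparameter search is included; the booster configuration is a
  fixed published operating point with config hooks for overrides.
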