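# Methods

## The classification problem

Given two curated sets of protein sequences over the 20-standard-residue
alphabet — a positive class (cancerlectins) and a negative class (other
lectins) — the toolkit builds a binary classifier usable on new sequences.
The pipeline is: tripeptide encoding → binomial confidence-level (CL)
ranking → subset selection → RBF-SVM → cross-validated evaluation.

## Tripeptide composition

A sequence of length `L` is scanned with overlapping windows of width 3
(step 1). Under the **strict** residue policy every window is valid and
the composition is `f_i = n_i / (L − 2)`; the two denominators `Σ n_i`
and `L − 2` coincide. Under the **drop-invalid-windows** policy,
sequences may contain non-standard residues (B, J, O, U, X, Z, `*`);
every window touching such a position is excluded and the denominator is
the number of valid windows, which keeps each row exactly normalised
rather than silently zero-filling corrupted entries. Strict is the
default because the encoding is defined on the 20-letter alphabet; the
drop policy exists because real UniProt records contain X residues and
rejecting them outright is often too blunt. A record with zero valid
windows is an error, not an all-zero row.

Columns are ordered lexicographically (`AAA` = 0 … `YYY` = 7999). The
ordering is a free choice — nothing downstream depends on it — but fixing
it makes exported matrices and feature lists portable across runs.

## Binomial confidence-level selection

Let `n_ij` be the total occurrences of tripeptide `i` in class `j`,
`N_i = n_i1 + n_i2`, `m_j = Σ_i n_ij` the total tripeptide occurrences in
class `j`, `M = m_1 + m_2` and `q_j = m_j / M`. `m_j` is an occurrence
total, not a count of distinct tripeptides: that reading makes the null
below well-posed for occurrence counts and makes `q_1 + q_2 = 1` hold
identically. Under the null that each of the `N_i` occurrences falls
into class `j` independently with probability `q_j`, the upper tail

    P(n_ij) = Σ_{m=n_ij}^{N_i} C(N_i, m) q_j^m (1 − q_j)^{N_i − m}

is computed via the regularised-incomplete-beta survival function
(`scipy.stats.binom.sf`), which is numerically stable for `N_i` well
beyond 10⁶; an exhaustive log-gamma summation oracle agrees to < 1e−10
over randomised grids with `N ≤ 1000`. `CL_ij = 1 − P(n_ij)`,
`CL_i = max_j CL_ij`, and the dominant class records which side is
over-represented.

Ranking is fully deterministic: descending `CL_i`, then ascending
min-class tail probability, then descending `N_i`, then lexicographic
tripeptide string. Tripeptides never observed (`N_i = 0`) are excluded
from the ranking — their CL is vacuous — and reported separately.
CL ties are detected with an absolute tolerance of 1e−12.

### Subset choice

Two mechanisms are provided. A **threshold** keeps every tripeptide with
`CL` *strictly* above the cut (strict inequality is an explicit choice;
the boundary convention is otherwise arbitrary). **Incremental feature
selection** walks the ranking downward, by default adding the whole block
of CL-tied features per step (a per-feature step is available), and
scores each cumulative subset by stratified k-fold (default 7)
cross-validated accuracy of the RBF-SVM. One fold split is drawn from the
seed and reused at every size, so curve points differ only in the feature
subset. The curve's argmax (first size on ties) is reported, but the
caller may fix a smaller size — with ~400 samples a subset of several
hundred features is already at the edge of what the sample size supports,
so trading a fraction of a percent of accuracy for far fewer dimensions
is often the right call.

During IFS the SVM hyperparameters stay fixed at the default operating
point rather than being re-tuned per subset size: re-tuning inside the
walk multiplies cost by the grid size and adds a second stochastic layer
to the curve. An optional grid search is available on the chosen subset
afterwards.

**Selection bias caveat.** The default protocol ranks features on the
full dataset and cross-validates only the classifier. On null data this
is measurably optimistic (we observe CV accuracy up to ~0.9 on pure noise
with 60 samples and thousands of candidate features), which is the
well-known feature-selection-bias artifact, not a defect of the
classifier or evaluator. The test suite therefore checks chance-level
calibration using feature sets chosen independently of the evaluated
labels (a ranking from an independent null draw, or the most-abundant
tripeptides by `N_i`), and separately documents the optimism of same-data
selection. For unbiased estimates the evaluators accept
`nested_rank_top=k` (CLI: `--nested-selection K`), which recomputes the
CL ranking inside every training fold so the held-out sequence never
influences the features used to predict it; on null data this variant
stays at chance where the default protocol does not.

## The SVM layer

scikit-learn's `SVC` (libsvm) with `K(x, y) = exp(−g‖x − y‖²)`. Defaults
`c = 2^11`, `g = 2^−13`; grid search evaluates `c ∈ 2^{−5..15}`,
`g ∈ 2^{−15..−5}` (factor-2 steps, 231 pairs) on a shared stratified fold
split, breaking accuracy ties towards the smaller `c`, then smaller `g`.

**Feature scaling.** Raw tripeptide frequencies have magnitude
`~1/(L − 2)` (a few 10⁻³). At `g = 2^−13` the kernel is then numerically
constant — pairwise `g·d² ≈ 10⁻⁷` — and the SVM degenerates to a
majority vote regardless of `c`. The trainer therefore applies the
standard LibSVM `svm-scale` protocol: each feature is mapped linearly to
[−1, 1] using its *training-set* min/max, the parameters are stored in
the model, and the same affine map is applied at prediction time (and
refitted inside every CV training fold, so no information leaks from
held-out samples). This is what makes the `(2^11, 2^−13)` operating
point meaningful; measured on a separable synthetic corpus it moves
7-fold accuracy from ~0.51 (chance) to ~0.998. Scaling can be disabled
(`SvmConfig(scale=False)`) for experiments with other kernels or
pre-scaled inputs. Constant columns map to a constant and are harmless.

No class weighting by default — imbalance is handled by reporting Sn and
Sp separately — though `class_weight="balanced"` is available. Trained
models store their exact ordered feature list and refuse permuted or
mismatched columns instead of silently reordering.

## Evaluation

`Acc = (TP + TN) / total`, `Sn = TP / (TP + FN)`, `Sp = TN / (TN + FP)`,
computed in exact rational arithmetic before conversion to float.
Zero-denominator cases raise an explicit `UndefinedMetricError` rather
than propagating NaN. The identity `Acc = (Sn·P + Sp·N)/(P + N)` holds
exactly for every report.

**Jackknife** (leave-one-out): each sample is predicted by a model
trained on the remaining `n − 1`; there is no randomness, so the report
is byte-identical across runs and independent of any seed. **k-fold**
uses stratified folds drawn from a seed, each sample predicted exactly
once; `k = n` reduces exactly to the jackknife. Confusion counts are
pooled over folds.

**ROC/AUC** follow the standard convention: false-positive rate on the
abscissa, true-positive rate on the ordinate, thresholds swept over the
distinct decision values (ties grouped into diagonal segments), area by
the trapezoidal rule. The curve is built from jackknife-pooled decision
values — each sample scored by the model that did not see it — and the
trapezoidal area equals the Mann–Whitney concordance probability to
1e−12 (property-tested against a brute-force pairwise count). Raw
decision values are used rather than calibrated probabilities, avoiding
an extra stochastic cross-validation layer.

## Synthetic data generator

The generator emulates the statistical structure the CL statistic is
designed to detect: class-conditional over-representation of specific
tripeptides. Negatives are i.i.d. draws from a background residue
distribution (uniform by default; empirical frequencies can be supplied).
Positives are background draws into which `Poisson(enrichment)` copies of
uniformly-chosen planted tripeptides are **overwritten** at uniformly
chosen non-overlapping start positions. Overwriting keeps lengths exactly
as drawn (so the `L − 2` denominator is controlled); non-overlap prevents
compound motifs from blurring the planted signal, while chance collisions
with background occurrences are kept as realistic noise. Placement
samples uniformly from the still-feasible start positions, and the
insertion count is capped at `(L − 2)/5` — the bound below which
non-overlapping placement is always satisfiable. All randomness flows
through numpy's PCG64 generator seeded from the spec, so datasets are
bit-reproducible across platforms.

Defaults (200+200 sequences, length 300, uniform background, 10 planted
tripeptides, enrichment 10) define the standard validation regime used
throughout the tests and the acceptance script: strong enough that the
ranking should place all 10 planted tripeptides in its top 20 and the
downstream jackknife should approach perfect separation, while the null
variant (enrichment ignored, identical background for both classes)
checks that nothing in the stack invents signal.

What the generator does **not** model: real lectin domain architecture,
homology and redundancy structure, residue autocorrelation, or
length–class correlations. Passing tests on synthetic corpora validate
the machinery — counting, ranking, selection, training, evaluation — not
the biological claim that tripeptide composition separates cancerlectins
from other lectins on any particular real dataset.

## Problem sizes

The test suite and acceptance script use scaled study conditions chosen
to exercise every code path at meaningful sample sizes: the standard
200+200/length-300 corpus for recovery and end-to-end checks (20
replicates for rate estimates), 100+100/length-150 for null calibration,
and 30–60 sequences per class for SVM-heavy unit tests. IFS walks are
capped (`max_size`) in tests; the full-walk contract is exercised on a
small corpus.

## Known limitations

- The CL statistic treats tripeptide occurrences as independent draws;
  overlapping windows violate this mildly (adjacent windows share two
  residues), which the binomial null ignores.
- Fold-internal selection (`nested_rank_top`) re-ranks by CL only; it
  does not re-run a full IFS walk inside each fold.
- Only `k = 3` is exposed; the counting machinery is k-agnostic
  internally but untested for other window widths.
- Model archives are joblib/pickle files: portable across sessions with
  the same library versions, not a long-term interchange format.
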