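# Methods

## The cascade model

The package predicts a graded multi-P450 inhibition outcome. The target is
the number *n* of inhibited isoforms among CYP1A2, CYP2C9, CYP2C19, CYP2D6
and CYP3A4, normalized to *y = n/5* ∈ [0, 1]. The predictor is a ladder of
Gaussian radial-basis-function (RBF) networks:

- **Screening.** For each descriptor *x_j* (min–max normalized to [0,1]), a
  1-input, 11-hidden-unit, 1-output RBF network is fitted to *y*; its output
  is the descriptor's provisional P450 inhibition score (PIS). Descriptors
  are ranked by Spearman ρ between that PIS and *y* over the whole modeling
  set; ρ > 0.4 admits a descriptor.
- **Ladder.** The top-ranked descriptor's unit starts the cascade. At each
  step every remaining admitted descriptor is tried as the second input of a
  2-11-1 unit whose first input is the current PIS; the candidate with
  maximal ρ is accepted iff its ρ strictly exceeds the current ρ
  (tolerance 1e-9, ties broken by lexicographic descriptor name).
  Construction stops when no candidate improves ρ or all admitted
  descriptors are used. Admission ρ is always computed on the full modeling
  set, not just a unit's internal training subset.

The cascade makes a strong architectural assumption: all information
gathered so far must flow through the one-dimensional PIS bottleneck. This
is exact for additive monotone signal structures (a running weighted average
is a sufficient statistic) but costs estimation efficiency relative to a
joint fit — see Limitations.

## Unit training

Each unit is trained on an internal random 2:1:1
(train/verification/testing) split, re-drawn per ladder step from a
deterministically derived seed:

- centers: k-means, k = 11, on the training-subset inputs, best of
  `restarts` (default 2) seeded initializations;
- widths: per center, the mean distance to its two nearest other centers,
  floored at 1e-6;
- readout: ridge least squares with an unpenalized bias; the ridge penalty
  is selected from the grid (1e-6, 1e-4, 1e-2, 1e-1, 1) by verification-set
  MSE;
- output: the raw linear readout is min–max rescaled by its training-output
  range and clipped to [0,1], so a unit's PIS can feed the next rung;
- `train_r` / `test_r`: Pearson correlations of the unit's PIS with *y* on
  the train and testing subsets, recorded for generalizability inspection.

Fitting requires at least 4 observations per hidden unit (n ≥ 44) and
non-constant inputs and target. Given identical inputs and seed the whole
pipeline is bit-reproducible, including the JSON model bundle.

## Data curation

Structure standardization removes water fragments, strips a configurable
list of common counter-ions, neutralizes the remaining fragment, and rejects
carbon-free structures as inorganic and multi-fragment residues as mixtures;
exotic salts are therefore rejected rather than guessed at. The molecular
weight filter is strict (< 800 Da) and is applied to weights recomputed from
the standardized structure. Call thresholds: AC50 ≤ 10 µM → inhibitor,
AC50 > 57 µM → non-inhibitor (the 57 µM boundary itself is indeterminate, as
the rule is a strict inequality); activity score > 40 → inhibitor,
score = 0 → non-inhibitor. A compound's count is defined only when all five
isoform calls are definite; otherwise the record is categorized `incomplete`
and excluded from modeling. Duplicate ids are reconciled by a caller-chosen
policy (`keep_first` or `strictest_call`); neither is claimed to match any
particular upstream database's behavior.

## Validation statistics

- Spearman ρ is the Pearson correlation of mid-ranks; its p-value uses the
  exact permutation distribution for n ≤ 9 and the t approximation
  otherwise.
- AUROC is the Mann–Whitney pair statistic (ties count ½); curve points are
  evaluated at thresholds midway between consecutive distinct scores, so the
  "optimal" Youden threshold (max sensitivity + specificity − 1, ties to the
  lowest threshold) falls midway inside a separating gap when one exists.
  The closest-to-(0,1) criterion was considered and rejected as the default
  because Youden's J is the conventional default in clinical ROC software.
- Paired ROC comparison uses DeLong's covariance estimate for correlated
  AUCs with a two-sided normal p-value.
- The 2:1:1 holdout uses largest-remainder rounding with remainder ties
  resolved in group order (train, verification, testing), so e.g. n = 10
  gives sizes (5, 3, 2). k-fold splits put the n mod k surplus items in the
  first folds.
- χ² on 2×2 tables is Pearson's statistic without continuity correction by
  default (flags switch on the correction or the McNemar paired variant).

## Similarity networks

Fingerprints are 2048-bit circular (Morgan radius-2, ECFP4-equivalent) bit
sets; any other generator can be plugged in by constructing `Fingerprint`
objects directly, and no claim is made that edge sets reproduce those of any
specific visualization plug-in. Edges are inclusive at Tanimoto ≥ 0.8;
clusters are connected components with the maximal-degree member (ties
lexicographic) as representative. The similarity-aware split sends every
compound with at least one neighbor to training, so the validation set is an
independent set with no edges into training; it is filled from the isolated
compounds toward the requested ratio and a warning reports shortfalls.

## The synthetic benchmark

`generate_qsar` uses an ordinal latent-variable design: latent propensity
z ~ N(0,1); each informative descriptor is a monotone link of z — linear,
sigmoid(2z), or softplus — standardized to unit variance, plus
N(0, noise_sd) noise, so `noise_sd` is a uniform noise-to-signal knob across
link shapes; remaining descriptors are independent standard normals; the
count is the number of fixed cut points below z (default: standard-normal
quantiles at equal 1/6 proportions, so both dichotomized tasks are
well-populated). The default benchmark is 600 compounds, 40 descriptors,
5 informative, noise_sd 0.5, seed 1, with a seeded half/half
modeling/holdout split stored in the dataset.

What the generator does *not* emulate: real descriptor distributions
(heavy-tailed, discrete, block-correlated), correlated noise descriptors,
multiple latent factors, or assay noise in the labels themselves. Passing
the planted-recovery tests therefore demonstrates that the pipeline
recovers sparse monotone structure at realistic signal strength — not that
any particular accuracy transfers to real compound collections.

## Numerical choices and degenerate inputs

Constant descriptors are flagged at normalization and dropped at
application; out-of-range values at prediction time clip to [0,1] (a model
trained on thousands of compounds will be applied to novel chemistry, so
unseen ranges are expected, and the PIS must stay in the unit interval).
Missing values exclude a compound from a unit's fit during screening; the
cascade build and prediction require complete values for the descriptors
they use and raise otherwise — no silent imputation. Labels are normalized
as count/5 (not dataset min–max): counts span 0–5 by construction, and
count/5 is stable on subsets. A degenerate unit whose raw outputs span less
than 1e-12 rescales against a floored range rather than dividing by zero.

## Benchmark observations

On the default benchmark the ladder recovers 4–5 of 5 planted descriptors
across seeds 1–10 with holdout ρ ≈ 0.93–0.96 and multi-task AUROC ≈ 0.98.
A single flat 11-unit RBF network over the same admitted descriptors — the
natural non-cascade baseline, trained identically — attains a slightly
*higher* median holdout ρ (≈ 0.956 vs ≈ 0.945 for the cascade, flat winning
most seeds). This is expected here: with only ~5 admitted, individually strong,
conditionally redundant descriptors driven by one latent factor, the jointly
fitted network is statistically efficient, while the greedy ladder pays a
selection penalty and compounds per-rung estimation error. The cascade's
practical advantage lies where joint fitting at fixed topology is
infeasible — thousands of candidate descriptors screened and fused one at a
time — a regime deliberately outside this desk-scale benchmark.

## Limitations

- The original training tool for this model family is proprietary; the
  k-means/ridge RBF trainer here is a standard, deterministic replacement,
  and no attempt is made to reproduce any specific published model's
  weights or dataset-specific metrics.
- Descriptor computation (e.g. PaDEL's 1,875 descriptors from 3D
  conformers) is an external, pluggable step; the package consumes numeric
  matrices.
- The ladder-extension candidate pool defaults to screened-in descriptors
  only; `extension_pool="all"` widens it to every descriptor, since the
  narrower pool is a design choice rather than a forced one.
- PIS clipping at [0,1] saturates a small fraction of extreme compounds
  (~1% on the benchmark), creating ties at the ends of the ranking.
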