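# Methods

`mirsig` re-implements, as a tested library, a miRNA-expression analysis of
pediatric acute myeloid leukemia (AML): normalization and variance
filtering of a TaqMan-array miRNA panel, unsupervised clustering of
patients, one-vs-rest SVM signature discovery per (cyto)genetic subtype
under double-loop cross-validation (DLCV), validation of the signatures on
an independent cohort from a different platform, and consensus
miRNA-target calling.  The original patient data are not publicly
deposited, so every stage is exercised on synthetic cohorts that emulate
the study's structure; this note records the models, the defaults and why,
and what the synthetic results do and do not establish.

## Data model

Expression is handled on the log2 scale as a features x samples matrix
(`ExpressionMatrix`) with a boolean mask of undetected cells.  Sample
annotation carries one subtype label per sample from a closed vocabulary —
`MLL` (11q23 rearrangements), `t_8_21`, `inv_16`, `t_15_17`, `CEBPA_dm`,
`NPM1`, and `other` — plus optional covariates, continuous (age, WBC) or
categorical (FAB class; tri-state mutation flags where "untested" is a
category of its own).  Cytogenetic notation such as `t(8;21)(q22;q22)` is
mapped onto the canonical tokens by an alias table; anything unrecognized
falls back to `other` with a warning.

## Normalization and filtering

Raw Ct values are converted to relative log2 expression by per-sample
median centering with a sign flip: `expr(f, s) = median_f'(Ct(f', s)) -
Ct(f, s)`, with undetected cells set to Ct 40 (the detection limit)
before the median.  One Ct cycle is one doubling, so the output is log2;
the per-sample median of the output is 0 by construction.  The method was
chosen as the standard TaqMan-array convention; the downstream filter is
invariant to the per-sample centering constant, so this choice does not
leak into feature selection.

The variance filter keeps a miRNA if at least one sample deviates from the
cohort geometric mean by a 6-fold factor or more.  Because the geometric
mean of linear abundances is the arithmetic mean of log2 values, the rule
is `max_s |x(f,s) - mean_s x(f,s)| >= log2(6)`, with an inclusive
comparison (the boundary case is kept; the original work does not say).
On the real cohort this retained 563 of 664 miRNAs; on default synthetic
cohorts it retains a similar fraction (~520/664 at seed 1), the removals
being low-variance noise features and fully censored low-abundance ones.

## Unsupervised clustering

Samples are clustered agglomeratively on `d = 1 - r`, where `r` is the
Pearson correlation between sample profiles, with Ward's minimum-variance
linkage.  Two documented choices:

* **Feature centering.** Each miRNA is mean-centered across samples before
  computing sample-sample correlations.  Without this, the per-miRNA
  baseline abundance — shared by every sample — dominates every pairwise
  correlation and subtype structure is invisible; centering makes the
  correlation reflect relative up/down regulation, which is also what the
  published heatmap displays.
* **Ward convention.** Ward linkage on a non-Euclidean dissimilarity is
  defined only up to convention.  The default `ward_d` applies the
  Lance-Williams minimum-variance update to the dissimilarities as given
  (R `hclust` "ward.D"); `ward_d2` applies it to their squares.  `ward_d`
  is realized through scipy by feeding sqrt-transformed distances and
  squaring the reported merge heights, which reproduces the ward.D merge
  sequence exactly (verified in the test suite against a naive
  Lance-Williams implementation).  Tie handling follows scipy's
  deterministic nearest-neighbor-chain order.

The number of flat clusters defaults to 14 as in the study, but is a plain
config value; no automatic selection is attempted because the study
describes none.  Cluster-label enrichment uses a one-sided hypergeometric
tail per (cluster, label level), continuous covariates use a two-sided
Wilcoxon rank-sum of in-cluster vs out-of-cluster values, and
Benjamini-Hochberg adjustment is applied within each label family.

## DLCV signature discovery

Each subtype with at least 10 samples is an independent binary task
(subtype vs rest).  One DLCV *run* is a fresh stratified 3-fold outer
split.  On each outer-training set:

1. an inner stratified 5-fold cross-validation evaluates signature sizes
   m over the grid {1, 2, 3, 5, 8, 12, 18, 27, 40, 60}: on each inner
   training split, features are ranked by absolute Welch t statistic
   (ties broken lexicographically; zero-variance features with a nonzero
   gap rank first) and the top m are standardized and fed to a linear
   soft-margin SVM (C = 1, unweighted); m* maximizes the pooled
   inner-test accuracy;
2. features are re-ranked on the full outer-training set, the top m* are
   standardized (training parameters only) and the SVM is refit;
3. the held-out outer fold is scored.

Per-run sensitivity, specificity, PPV, NPV and accuracy come from the
run's pooled confusion counts; the report averages per-run metrics over
runs (100 by default; undefined ratios are NaN-flagged, never coerced to
zero).  A feature's selection frequency is the fraction of outer-training
fits whose final model contained it; the subtype signature is the set of
features with frequency >= tau (default 0.5), capped at the median m*.
Directions (up/down) are the sign of the full-cohort in-group minus
out-group mean.  The per-subtype signatures are consolidated into a
de-duplicated union (the study's 47-miRNA set is such a union).

Reconstruction choices (the original construction details are not public):

* **Inner score = pooled accuracy**, the same quantity the outer loop
  reports.  Class-balanced inner scores let overfit large-m models win by
  chance on null data, destroying the procedure's null calibration.
* **Ties toward the largest m.**  When inner accuracy saturates (common
  under strong signal), the data cannot distinguish sizes; the larger set
  is preferred because redundant signatures survive cross-platform feature
  loss, which the validation stage explicitly faces.  A consequence worth
  knowing: under saturated signal the chosen signature can carry
  passenger features beyond the planted ones, so consolidated union sizes
  exceed the sum of true signature sizes.
* **Unweighted SVM (class_weight=None by default).**  With the small
  subtype groups (11-36 of 165), an unweighted SVM degrades gracefully to
  majority-class behavior when there is no signal (low sensitivity, high
  specificity, accuracy near prevalence) — the same asymmetry the study
  reports for its smallest groups.  Balanced weighting is available via
  config.
* **One run = one outer reshuffle**; 100 runs are 100 stratified
  reshuffles of the outer 3-fold split.

All stochastic stages derive their fold seeds deterministically from a
single configured seed, so identical (data, config, seed) yields
byte-identical reports.  Outer-test samples cannot influence ranking,
standardization, or fitting of their own fold: fold training is a pure
function of the training rows and the fold seed (asserted by a
perturbation test).

## Cross-platform validation

Per subtype: the signature is intersected with the test platform's feature
names after canonicalization (lowercase, whitespace and organism prefix
stripped; the star strand `miR-126*` and arm suffixes `-3p/-5p` remain
distinct features).  Both cohorts are restricted to the shared features
and each cohort is standardized per feature within itself — the single
harmonization step, which makes validation exactly invariant to any
per-feature additive platform offset (config-off-able).  The SVM is
trained on the full training cohort and every test sample is scored.
Subtypes with too few positive test samples (default 5) are reported as
"insufficient", and subtypes with no measurable signature miRNAs as
"untestable"; neither is silently scored, mirroring the study's exclusion
of its smallest group from validation.

## Target consensus

A (miRNA, gene) pair is a consensus target when at least 3 of the (by
default 5) prediction databases report it; both numbers are configurable
and the database count is data-driven.  Databases are two-column TSV
files; only synthetic fixtures ship with the package, since real
prediction databases are versioned external resources.  Called targets
are screened on paired expression data by Spearman rank correlation
across shared samples (robust to log/linear monotone ambiguity; Pearson
by flag), with BH adjustment over tested pairs and a `consistent` flag
for negative correlation — the repression model predicts inverse
correlation, and violations are reported, not suppressed.

## Synthetic cohorts

The generator plants the study's structure: 165 samples in groups of
36/21/17/12/11/11 plus 57 "other"; 664 miRNAs; per-subtype signature
blocks of 37/14/17/14/18/5 features, disjoint by default (a config switch
allows the overlap seen between the two core-binding-factor subtypes).
Values are `baseline(f) + signed effect + noise` on the log2 scale:

| parameter | default | why |
|---|---|---|
| `effect_log2` | log2(6) ~ 2.585 | one filter-threshold fold; the study's own selection criterion |
| `direction_mix` | 0.5 | signatures mix up/down members; real ratios are presets, not assumptions |
| `baseline_sd` | 2.0 | log2 abundance spread across miRNAs on expression arrays |
| `noise_sd` | 1.0 | per-measurement biological + technical variation on the log2 scale |
| `missing_rate` | 0.02 | a small undetected fraction after quality control |

Undetected cells are **left-censored**: the lowest `missing_rate` fraction
of values falls below the detection limit and is imputed at the cohort
floor (the censoring threshold).  This is how Ct arrays actually lose
data — low-abundance transcripts go undetected; undetected cells are not
random high-abundance measurements.

What the generator does *not* emulate: correlated co-regulation among
non-signature miRNAs, lineage gradients, batch structure, or heavy-tailed
noise.  Real cohorts carry pervasive covariation beyond the sparse planted
blocks, which helps clustering and hurts specificity of selection; passing
recovery tests here therefore demonstrates correctness of the machinery
under the stated model, not expected field performance on patient data.
In particular the headline numbers of the original study are computed on
an undeposited cohort and are context, not targets.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run DLCV at 25 runs (null
calibration at 10 runs over 10 seed-cohorts), clustering recovery over 10
seed-cohorts at k = 7 with `effect_log2 = 3` (the strong-signal setting
also used for cross-platform checks), and cross-platform validation over
10 cohort pairs at keep_fraction 0.6 and shift_sd 2.  These sizes were
chosen as the smallest giving stable Monte-Carlo estimates of the bounds
being asserted.

## Known limitations

* The DLCV internals (fold counts, ranking statistic, size grid,
  consolidation rule) are a documented reconstruction, config-exposed so
  alternative readings are one flag away; the original supplementary
  construction details were not available.
* Ward-on-correlation clustering of sparse planted signatures is
  information-limited: with only 5 informative features out of ~660
  retained (the smallest subtype at default effect size), within-group
  correlation gains (~0.04) are at the level of correlation sampling
  noise, and recovery of that subtype by clustering is not reliable —
  classification, which selects features, does not share this limit.
* Enrichment p-values are not calibrated for post-clustering selection
  (clusters are chosen from the same data being tested); they are used as
  ranking scores, as in the original analysis.
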