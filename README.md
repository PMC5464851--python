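# mirsig

Subtype classification of pediatric acute myeloid leukemia (AML) from
miRNA expression profiles: a reusable, tested implementation of the full
analysis pipeline — Ct normalization, geometric-mean fold filtering,
Ward/Pearson unsupervised clustering with subtype-enrichment testing,
double-loop cross-validated (DLCV) one-vs-rest SVM signature discovery for
six (cyto)genetic subtypes, cross-platform validation on an independent
cohort, and consensus miRNA-target analysis — together with a
synthetic-cohort generator so every stage is testable without patient
data.

It is intended for computational biologists who want to run, audit, or
extend this class of signature-discovery analysis: the statistical
machinery is the deliverable, exercised end-to-end on synthetic cohorts
that emulate a 165-sample, 664-miRNA pediatric AML study.

## The method in brief

A log2 expression matrix (miRNAs x samples) is filtered to miRNAs that
deviate from the cohort geometric mean by ≥ 6-fold in at least one sample,
i.e. `max_s |x(f,s) − mean_s x(f,s)| ≥ log2 6`.  Patients are clustered on
`d = 1 − r` (Pearson correlation of feature-centered profiles) with Ward
linkage, and clusters are tested for enrichment of subtype labels
(one-sided hypergeometric) and clinical covariates (Wilcoxon rank-sum),
with Benjamini–Hochberg adjustment per family.

For each subtype *g* with ≥ 10 samples, a one-vs-rest linear SVM is built
under double-loop cross-validation: each run draws a stratified 3-fold
outer split; on each outer-training set an inner stratified 5-fold CV
picks the signature size m\* from a fixed grid (features ranked by
absolute Welch *t*); the top-m\* model is refit and scored on the held-out
fold.  Per-run pooled confusion counts give sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), PPV, NPV and accuracy, averaged over runs.
Signature stability is the selection frequency — the fraction of fits
whose final model contained a miRNA — and the subtype signature is the set
with frequency ≥ τ (default 0.5), capped at the median m\*.  Validation on
a second platform restricts signatures to the platform intersection,
standardizes each cohort per feature within itself, trains on the full
first cohort and scores the second.  A gene is a consensus target of a
miRNA when ≥ 3 of 5 prediction databases report the pair; called pairs
are screened for the expected inverse miRNA–target correlation (Spearman).

See `docs/methods.md` for assumptions, parameter rationale, and the
documented reconstruction choices.

## Worked example

Simulate a strong-signal cohort, filter, cluster, and discover signatures
(the `mirsig` console script wraps the library; every stage also has a
Python API):

```sh
mirsig simulate --out demo/sim --seed 3 --effect-log2 3.0 --second-platform
mirsig preprocess --expression demo/sim/expression.tsv --out demo/prep --skip-normalize
mirsig cluster --expression demo/prep/filtered.tsv \
    --annotation demo/sim/annotation.tsv --out demo/clust --k 7
mirsig dlcv --expression demo/sim/expression.tsv \
    --annotation demo/sim/annotation.tsv --out demo/dlcv --runs 10 --seed 3
```

which prints

```
wrote cohort (664 features x 165 samples) to demo/sim
retained 513 of 664 miRNAs
cut into 7 clusters; 7 enrichment rows at adj p<0.05
MLL: acc 100.0% sens 100.0% spec 100.0% signature size 49
t_8_21: acc 100.0% sens 100.0% spec 100.0% signature size 39
inv_16: acc 100.0% sens 100.0% spec 100.0% signature size 43
t_15_17: acc 100.0% sens 100.0% spec 100.0% signature size 34
CEBPA_dm: acc 100.0% sens 100.0% spec 100.0% signature size 39
NPM1: acc 99.4% sens 90.9% spec 100.0% signature size 10
```

Reading this: the fold filter kept 513 of 664 miRNAs (it removes
low-variance noise and fully censored low-abundance features); cutting the
Ward tree at k = 7 recovered clusters in which each planted subtype is
significantly enriched; and DLCV at 10 runs classifies every subtype
nearly perfectly on this strong-signal cohort — the smallest group (NPM1,
11 of 165 samples) shows the lowest sensitivity, the same asymmetry the
clinical study reports.  Per-subtype metrics, selection frequencies, and
the chosen signatures land in `demo/dlcv/dlcv_report.json` and
`signatures.json`.  Validating those signatures on the platform-shifted
replicate cohort (60% feature overlap emulation):

```sh
mirsig validate --train-expression demo/sim/expression.tsv \
    --train-annotation demo/sim/annotation.tsv \
    --test-expression demo/sim/expression_platform2.tsv \
    --test-annotation demo/sim/annotation.tsv \
    --signatures demo/dlcv/signatures.json --out demo/val
```

```
MLL: acc 100.0% (32 shared miRNAs)
NPM1: acc 100.0% (9 shared miRNAs)
...
```

Only the signature miRNAs present on the second platform are used; per-
cohort feature standardization makes the result exactly invariant to
additive platform offsets.

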