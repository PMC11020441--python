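# Methods

## Scope and data model

The pipeline models recurrent chromosome-arm aneuploidy as a supervised
classification problem over (arm, context) instances, where a context is a
cancer type or a cancer cell-line (CCL) group.  The default arm universe is
the 39 autosomal arms (22 autosomes × 2 minus the five acrocentric p-arms
13p/14p/15p/21p/22p, which carry no annotated protein-coding genes) and 24
cancer contexts, giving the 936-instance grid.  All tables are tab-delimited
UTF-8 text with mandatory headers; gene and context identifiers are opaque
strings and arm identifiers follow the `<chrom><p|q>` convention.

## Event labeling

An arm is called gained (lost) in a context when the q-value of its
recurrent amplification (deletion) is below the significance threshold α.
α = 0.05 for tumor cohorts and α = 0.15 for CCL groups — CCL cohorts are
far smaller, so the arm-level significance screen is run at a relaxed
threshold.  When both directions are significant the lower q-value decides;
a q-value tie is broken by the more frequent event.  A tie in both q-value
and frequency cannot occur in real GISTIC output; it resolves
deterministically to *gain* with a logged warning, so that labeling is a
total function.  NaN q-values are a hard error unless the policy explicitly
maps them to 1.0.  A whole chromosome is called gained (lost) only when
*both* of its arms pass the threshold in that direction; for acrocentric
chromosomes with a single informative arm the call falls back to the q-arm
alone.  This single-arm fallback is this package's documented choice for a
case the arm-level rule leaves open.

Monotonicity holds by construction: lowering α can only turn events into
neutral calls, never the reverse.

## Feature engineering

Twenty features in three categories (3 chromosome-arm, 4 cancer-tissue, 13
normal-tissue), registered in a single ordered registry that is the source
of truth for column naming and order.

* **Tissue-relative z-score.** For a gene g with per-tissue values v over a
  tissue set T, z_g^t = (v_g^t − mean) / σ with σ the *population* SD of
  the full tissue vector (divide by |T|).  The population convention is
  deliberate — the tissue set is the complete universe being standardized,
  not a sample from a larger one — and is isolated in one function so the
  sample convention would be a one-line change.  Zero-spread genes map to
  all-zero z-scores.
* **Gene-to-arm aggregation.** Per feature and tissue, genes are ranked by
  their (tissue-relative) score descending, ties broken by gene identifier
  for determinism; the arm value is the median of the top ⌈0.1·n⌉ genes.
  The ceiling guarantees a non-empty top set on small arms.  The top-decile
  selection runs over all genes on the arm with a defined score (not only
  tissue-expressed genes); the fraction is configurable (`top_fraction`).
* **Density features** (OG/TSG/essential densities, tissue-specific-gene
  density, cancer-specific essential density) are fractions of qualifying
  genes out of all protein-coding genes on the arm.  A gene is essential
  when its essentiality probability exceeds 0.8; cancer-specific essential
  genes are those with oriented CRISPR score > 0.5 in the matched cell
  line.  Dependency scores are negated ("oriented") so more essential genes
  score higher.
* **Cancer expression / essentiality** read-outs are per-gene medians that
  upstream processing computes from samples where the gene's host arm is
  neutral, to avoid circularity between the event and its own expression
  footprint; the `neutral_restricted_median` operation implements this
  restriction for sample-level input.
* **PPI features.** Per gene and tissue: the number of interaction partners
  expressed in the tissue (TPM > 1), the number preferentially expressed
  there (preferential-expression score > 2), the number expressed there and
  in ≤ 20% of tissues, and the median differential-PPI score of the
  partners.  A gene not itself expressed in the tissue gets all four values
  set to 0.  Differential PPI scores and differential process activity are
  already tissue-relative and are not re-standardized.
* **Paralog compensation.** Raw per-tissue ratio (gene TPM + ε)/(paralog
  TPM + ε) with ε = 0.01 (pseudocount chosen to avoid division by zero
  without distorting expressed genes), z-scored across tissues and negated,
  so higher values mean relatively higher paralog expression, i.e. stronger
  potential buffering.  The raw ratio orientation is gene/paralog; the final
  semantics (higher = more compensation) is what downstream code relies on.
  Note the exact antisymmetry score(g→p) = −score(p→g) holds only on ranks
  for ratio-based scores (it would be exact for log-ratios); the tests
  assert the rank form.
* **Development features.** Organ expression time courses are united into
  three periods — fetal (4–20 weeks post-conception), childhood
  (newborn/infant/toddler) and young (school/teenager/young adult) — by
  per-period medians, plus a variability feature (population SD across the
  three period medians), all z-scored across organs.
* **Table assembly.** Each context draws its cancer features from its own
  expression/dependency columns and its normal-tissue features from the
  matched tissue (and organ) in the context map; contexts without a matched
  tissue are dropped with a log message.  Normal-tissue sub-region columns
  (`tissue|subregion`) are collapsed by median at the arm-feature level,
  after aggregation.  Transcriptomic feature columns are re-standardized
  within each tissue (some tissues — testis, whole blood — are globally
  distinct, and a per-tissue z removes that offset).  Remaining missing arm
  values are imputed by the feature's column median (tree models in this
  design require complete rows); every imputed cell is recorded in
  `table.attrs["imputed"]`.  A feature family absent from a bundle
  altogether (e.g. developmental organs for CCL cohorts) imputes to 0 so the
  20-column registry — and hence model transferability — is preserved.
  The assembly is fully deterministic: no randomness anywhere.

## Models and evaluation

Gain and loss are modeled separately as event-vs-neutral binary problems
(one-vs-rest variants keep all instances); whole-chromosome analogues are
the trisomy and monosomy tasks.  Five methods: logistic regression,
gradient boosting, XGBoost, random forest, bagging — at common library
defaults, since hyperparameter tuning changes performance only marginally
at this data size.  Evaluation is stratified 10-fold cross-validation with
mean auROC and auPRC, against the positive-class prevalence as the no-skill
precision baseline.  A single seed per run governs fold assignment, method
RNG and tuning sampling.  Randomized hyperparameter search
(`tune_hyperparameters`, default n_iter = 200, 10-fold) optimizes
precision.  `apply_pretrained` evaluates a tumor-trained model on a CCL
feature table after verifying registry identity.

## Interpretation

Attributions are exact path-dependent TreeSHAP values.  The `shap` package
is not a dependency: `aneuml.treeshap` implements the polynomial-time
path-dependent algorithm for sklearn trees (verified in the test suite
against a brute-force subset-enumeration Shapley oracle on small trees, and
exact to ~1e-15 additivity), XGBoost models use the library's native
`pred_contribs` (float32, additive to ~1e-6), and logistic regression uses
the exact linear decomposition w_j(x_j − mean x_j) on the margin scale.
Global importance is mean |attribution|; ranking is invariant to instance
order.

*Directionality*: instances are split at the feature's median value (ties
at the median go to the lower half, for determinism); the feature points to
the *event* when the mean attribution of the top half is positive, else to
*neutrality*.  The mean (rather than the majority sign) is used because it
weights instances by attribution magnitude, matching how global importance
is computed.  *Driver instances*: per top-5 feature, the top ⌈10%⌉ of
positive and of negative attributions.  *Exclusion robustness*: instances
that drive ≥ 3 of the top-5 features are removed, the model is refitted and
re-ranked, and per-feature rank displacement is reported.

## Synthetic cohorts

The generator emulates all seven input families as one self-consistent
bundle.  Genes are placed on arms (50–300 per arm, log-uniform); OG/TSG
flags and essentiality probabilities are drawn against per-arm
Beta-distributed density targets, so arm densities genuinely vary;
expression is log-normal (baseline log2 TPM ~ N(3.5, 1.5), so most genes
pass the TPM > 1 expression filter) with per-(arm, tissue) and per-(arm,
cancer) shifts; dependency scores decrease linearly with essentiality
probability; PPIs, preferential-expression, differential-PPI, process
activity and eQTL tables are noise unless planted otherwise; a
configurable fraction (0.6) of genes receives a random paralog, and
paralog-bearing genes are relatively under-expressed where their arm's
compensation shift is high, which is what the compensation feature detects.

Labels follow a two-stage logistic model on *standardized realized* arm
features: log-odds(gain) = b_g + Σ c_{f,gain} z_f, then, conditionally,
log-odds(loss) = b_l + Σ c_{f,loss} z_f.  Default coefficients mirror the
negative-selection structure of the real landscape: TSG density → gain
−2.0 (dominant), OG density → loss −1.5, cancer expression → gain +1.0,
paralog compensation → loss +1.0.  The intercepts (−2.4, −0.55) were chosen
once so the default label mix approximates the real tumor cohort's
proportions (~21% gain, ~33% loss, ~46% neutral).  5% of labels are flipped
to a random other class as noise.  Labels are then encoded into GISTIC-like
records with a guaranteed q-value gap (events q < α/2, non-events q > 2α),
so the labeling module reproduces the intended labels exactly — separating
labeling-logic tests from noise-model tests.  A CCL bundle re-noises the
same truth for the first 10 contexts at α = 0.15, without developmental
organs.  All randomness flows from one seed through named streams (one per
table family), so adding a table never perturbs existing draws.

What the generator does *not* emulate: real genome coordinates or gene
symbols, realistic correlation structure between feature families, arm-arm
event co-occurrence, intratumor heterogeneity, or TCGA marginal
distributions.  Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and sensitive at realistic scale — not that
the real-data conclusions follow; those require the external resources.
One consequence worth noting: the planted compensation and expression
shifts are tissue-specific with mean ≈ 0 per arm, so the arm-level
correlation screen (which takes medians across contexts) shows little
signal for them even though the classifiers and SHAP recover them — the
correlation utility is most informative for context-independent features
such as the gene-density ones.

## Numerical choices and problem sizes

Zero-variance genes z-score to 0; top-decile ties break by gene id;
directionality ties at the median go to the lower half; driver deciles use
ceilings; BH adjustment is the standard step-up with monotone enforcement
(via statsmodels); chi-square is asymptotic without continuity correction
(conventional for 3×3 tables at these counts, with a logged warning when an
expected cell is < 5).  Cross-validation requires k ≤ minority-class count.
The acceptance script uses 10 seeds each for the null-calibration and
recovery summaries and 10-fold CV throughout; the test suite uses 20 seeds
for the same properties at full cohort size, and a reduced cohort (8 arms ×
6 contexts) for unit tests.

## Known limitations

* The published real-data headline numbers (auROC 74%/70%, the printed
  Spearman coefficients, the 199/307/430 label split) depend on external
  TCGA/GTEx/DepMap downloads and are reproduced here only as arithmetic
  identities (prevalence baselines) or as qualitative analogues on
  synthetic cohorts.
* Path-dependent TreeSHAP inherits the usual caveats: attributions assume
  the tree's cover distribution approximates the feature distribution, and
  correlated features share credit unpredictably.
* The paralog analysis conditions on a single best-matching paralog per
  gene; many-to-many paralogy is out of scope.
* eQTL and process-activity scores arrive precomputed; the pipeline only
  standardizes and aggregates them.
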