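# aneuml

Interpretable machine-learning analysis of chromosome-arm aneuploidy
patterns in cancer.

Recurrent gains and losses of whole chromosome arms are a hallmark of
cancer, and their patterns are strongly tissue-specific: an arm that is
recurrently lost across most cancer types (e.g. 13q) can be recurrently
gained in another (colorectal cancer). `aneuml` implements, as a tested and
reusable pipeline, an analysis that asks *which genomic and tissue
properties shape these patterns*, and in particular how much of the
landscape is explained by negative selection (avoiding harmful events)
versus positive selection (favoring beneficial ones).

The pipeline is aimed at computational cancer-genomics researchers.  It
works from tab-delimited tables emulating standard resources (GISTIC2.0
arm-level significance calls, GTEx-like normal-tissue expression, TCGA-like
cancer expression medians, DepMap-like CRISPR/RNAi dependency screens, PPI
and developmental-expression annotations) and ships a synthetic-cohort
generator with planted effects, so every stage runs and is testable without
any external download.

## The method

1. **Labeling.** Each (chromosome-arm, cancer-type) instance is called
   *gained* if the GISTIC q-value of its recurrent amplification is below
   α = 0.05, *lost* if the deletion q-value is below α, and *neutral*
   otherwise; when both are significant, the lower q-value wins, with the
   more frequent event breaking ties.  Cell-line cohorts use α = 0.15, and a
   whole chromosome is called only when both of its arms agree.

2. **Feature engineering.** Twenty features per instance in three
   categories — chromosome-arm (3: oncogene, tumor-suppressor and
   essential-gene densities), cancer tissue (4: expression and dependency
   read-outs), normal tissue (13: expression, PPIs, tissue-specific genes,
   process activity, eQTL, paralog compensation, developmental expression).
   Per-tissue gene values v are made tissue-relative by a z-score over the
   tissue set T,

   z_g^t = (v_g^t − mean_{t′∈T} v_g^{t′}) / σ(v_g),   σ = population SD,

   and each arm receives the median score of its top-decile genes (density
   features use the fraction of qualifying genes).  The paralog-compensation
   score of a gene is the negated tissue-relative z of the expression ratio
   (gene + ε)/(paralog + ε), so higher values mean stronger buffering by the
   paralog.

3. **Modeling.** Separate binary gain and loss models (event vs neutral)
   with five methods — logistic regression, gradient boosting, XGBoost,
   random forest, bagging — scored by stratified 10-fold cross-validated
   auROC and auPRC against the prevalence (no-skill precision) baseline.

4. **Interpretation.** Exact path-dependent TreeSHAP attributions (authored
   in `aneuml.treeshap` for sklearn ensembles, native `pred_contribs` for
   XGBoost) give per-feature importance (mean |SHAP|), a directionality call
   (do the top-50% feature values push toward the event or toward
   neutrality?), driver-instance deciles, and an exclusion-robustness
   re-analysis.

5. **Association.** Spearman correlations of per-arm feature medians with
   gain/loss frequencies under Benjamini–Hochberg adjustment, plus the
   paralog-compensation analysis: recurrently lost genes are grouped by
   minimal CRISPR dependency score (essential ≤ −0.5, non-essential ≥ −0.3)
   and the arm status of their paralogs is tested for independence
   (chi-square) alongside a KS comparison of dependency-score distributions.

## Worked example

```python
import pandas as pd
from aneuml import synthetic, features, labeling, modeling, interpretation

cohort = synthetic.generate_cohort(synthetic.GeneratorConfig(seed=1))
labels = labeling.label_table(cohort.records)
print("label counts (gain, loss, neutral):", labeling.label_counts(labels))

lab = pd.Series({(l.arm_id, l.context_id): l.label for l in labels}
                ).rename_axis(["arm", "context"])
table = features.build_feature_table(cohort.bundle)
print("feature table:", table.shape)

X, y = modeling.assemble_task(table, lab, "gain")
res = modeling.cross_validate(
    modeling.ModelSpec("gradient_boosting", seed=1), X, y, k=10)
print(f"gain model: auROC={100*res.auroc:.0f}% auPRC={100*res.auprc:.0f}% "
      f"(expected {100*res.baseline:.0f}%)")

model = modeling.fit_model(modeling.ModelSpec("gradient_boosting", seed=1), X, y)
summary = interpretation.compute_shap(model, X)
directions = interpretation.feature_direction(summary.values, X)
top = pd.DataFrame({"mean_abs_shap": summary.mean_abs.round(3),
                    "direction": directions}
                   ).sort_values("mean_abs_shap", ascending=False)
print(top.head(5))
```

Output:

```
label counts (gain, loss, neutral): (205, 319, 412)
feature table: (936, 20)
gain model: auROC=81% auPRC=73% (expected 33%)
                        mean_abs_shap direction
tsg_density                     1.187   neutral
tcga_expression                 0.680     event
paralog_compensation            0.196     event
gtex_expression                 0.169   neutral
devel_expression_fetal          0.163     event
```

Reading the output: the synthetic cohort has the full 39 × 24 = 936
instance grid with a gain/loss/neutral mix close to the real tumor cohort.
The gain model clearly beats its 33% no-skill precision baseline.  The
interpretation recovers the generator's planted structure: tumor-suppressor
density is the dominant feature and points toward *neutrality* (arms dense
in TSGs resist gain — negative selection), while cancer expression points
toward the *event* (highly expressed arms tend to be gained).

The same stages are available from a shell:

```bash
aneuml simulate --seed 1 --out-dir cohort/
aneuml label --input cohort/gistic.tsv --out labels.tsv
aneuml build-features --in-dir cohort/ --out features.tsv
aneuml train --in-dir cohort/ --task gain --method all --out metrics.tsv
aneuml interpret --in-dir cohort/ --task gain --out-prefix shap
aneuml correlate --in-dir cohort/ --out correlations.tsv
aneuml paralog-analysis --in-dir cohort/ --context C01 --out paralog.tsv
```

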