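# mycsig

Directional oncogene-signature scoring, immune gene-set scoring and
survival association for bulk transcriptomic cohorts.

## The problem

Tumors driven by the MYC oncogene tend to be immunologically "cold": they
express less antigen-presentation machinery (MHC-I, *B2M*, *NLRC5*), carry
fewer tumor-infiltrating leukocytes, and respond poorly to immune
checkpoint blockade. Quantifying a tumor's MYC activity from expression
data — and relating it to immune infiltration and patient outcome — takes
a reproducible chain of steps that is usually re-implemented ad hoc for
every cohort. `mycsig` packages that chain for analysts working with
genes × samples expression matrices:

1. **Signature derivation** — intersect differential-expression results
   from several MYC-driven model datasets, keeping genes that are
   significant in every dataset with a concordant sign of log2 fold
   change; map mouse symbols to human via a user-supplied ortholog table.
   The result is a *directional signature*: genes with +1 (up-regulated by
   MYC) or −1 (down-regulated) labels.
2. **Per-sample scoring** — after log2 transform and per-gene
   median-centering, each sample's score is the Pearson correlation
   across signature genes between its centered expression *x* and the
   directionality vector *d* ∈ {+1, −1}ᵖ:

   score(j) = corr(x₍·j₎, d) ∈ [−1, 1].

   Immune gene sets are scored as the mean of their member genes
   (e.g. a 60-gene TIL set) or by single-sample GSEA (ssGSEA), the
   rank-weighted running-sum enrichment statistic with exponent
   α = 0.25.
3. **Association** — Pearson/Spearman correlations between scores (and
   individual genes such as *CD274* or *B2M*), with Benjamini–Hochberg
   FDR control per declared family of tests.
4. **Survival** — dichotomize samples at a cut-point (0 by default:
   High > 0, Low ≤ 0), then Kaplan–Meier curves, the two-group log-rank
   test, and a binary-covariate Cox proportional-hazards model
   (Breslow or Efron ties).

A seeded synthetic-cohort generator with a latent per-sample activity
variable provides planted ground truth for every stage, so the whole
pipeline is testable without controlled-access patient data.

The scorers are scikit-learn transformers (`DirectionalScorer`,
`GeneSetMeanScorer`, `SsgseaScorer`, `Dichotomizer`) and compose with
sklearn pipelines; module-level functions wrap them for
`ExpressionMatrix` inputs, and a CLI (`mycsig`) wraps both.

## Worked example

```python
from mycsig import (CohortConfig, generate_cohort, median_center,
                    score_direction_correlation, score_mean, dichotomize,
                    correlate, cox_binary, logrank_test, km_estimate,
                    median_survival)

cohort = generate_cohort(CohortConfig(seed=7))   # 200 samples, 2000 genes
m = median_center(cohort.expression)
myc = score_direction_correlation(m, cohort.signature)
imm = score_mean(m, cohort.immune_set)
r = correlate(myc.scores, imm.scores)

groups = dichotomize(myc, cutpoint=0.0)
table = cohort.survival.with_groups(groups)
cox, lr = cox_binary(table), logrank_test(table)
```

printing, for this seed:

```
MYC score range: -0.981 to 0.987
Pearson r = -0.903, q = 1.12e-74 (n = 200)
High n=101, Low n=99
Cox HR = 2.51 (95% CI 1.79-3.52), log-rank p = 4.88e-08
median survival High: 33 days
median survival Low: 90 days
```

The per-sample score spans nearly the full [−1, 1] range because
signature genes move strongly with the latent activity; the immune mean
score is strongly anticorrelated with the MYC score (the generator plants
a coupling of −1); and High-score samples experience events about 2.5×
faster, with correspondingly shorter median survival.

The same analysis runs from the shell:

```bash
mycsig simulate --seed 7 --outdir sim/
mycsig preprocess --expr sim/expr.tsv --scale log2 --no-log2 --out sim/centered.tsv
mycsig score-direction --expr sim/centered.tsv --signature sim/signature.tsv --out sim/scores.tsv
mycsig dichotomize --scores sim/scores.tsv --out sim/groups.tsv
mycsig survival --surv sim/survival.tsv --groups sim/groups.tsv --out sim/surv.json
```

or end-to-end from a YAML config with `mycsig run --config pipeline.yaml`.

## What it does not do

No microarray probe-level processing, RNA-seq quantification or
differential-expression calling (DE tables are inputs); no live ortholog
database queries; no multivariable Cox models or responder regressions.
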