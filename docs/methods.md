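# Methods

## Directional signature scoring

A directional signature is an ordered set of genes with labels
d_g ∈ {+1, −1}: +1 for genes up-regulated by the driver (here MYC), −1
for genes it down-regulates. Given a genes × samples matrix on the log2
scale with each gene's across-sample median subtracted, the score of
sample *j* is the Pearson correlation over the signature genes present in
the matrix between the sample's centered expression x₍·j₎ and the
direction vector d. The score is therefore scale-free, lies in [−1, 1],
is invariant to per-sample affine transforms x → a·x + b with a > 0, and
is exactly negated when every direction flips. Median-centering matters:
it makes each gene's values comparable to a symmetric ±1 target, so a
sample scoring +1 has its up-genes above and its down-genes below the
cohort median in perfect rank harmony with the signature.

Samples whose expression over the overlapping genes has zero variance
receive a missing score (the correlation is undefined); they are never
silently scored 0, which would bias downstream correlations. Scoring
requires at least `min_overlap` signature genes in the matrix (default 3,
with a loud warning below 10) and both signs present in the overlapping
direction vector.

## Immune gene-set scores

Two per-sample summaries of a gene set are provided.

**Mean-of-genes** — the arithmetic mean of the member genes' values on the
matrix's current scale, the conventional immune-cell infiltration score
(tumor-infiltrating lymphocyte sets, per-cell-type marker sets). Absent
genes are dropped with a warning and the genes actually used are recorded.

**ssGSEA** — a rank-based enrichment score computed per sample. All N
genes are ranked by expression (highest → rank N; ties get average
ranks). Walking positions from the top rank down,

    ES = Σᵢ [ P_in(i) − P_out(i) ],
    P_in(i)  = Σ_{members at position ≤ i} rank^α / Σ_{members} rank^α,
    P_out(i) = #(non-members at position ≤ i) / (N − |set|),

with weighting exponent α = 0.25 by default. The statistic depends only on
within-sample ranks, so any strictly increasing per-sample transform of
expression leaves it unchanged; this makes it robust to per-sample scale
differences and is the property the tests enforce. Optional normalization
divides all samples' scores by (max − min) across the cohort; it defaults
to off, and analyses that only correlate scores are unaffected by this
linear rescaling. Ties are broken by average rank first, with the α-power
applied to the (possibly fractional) rank value, and tied positions are
walked in stable gene order; the brute-force oracle in the test suite
implements the identical policy independently.

## Signature derivation and ortholog mapping

`derive_shared_signature` intersects differential-expression tables from
k ≥ 2 model datasets: a gene enters the signature iff it is significant
(padj ≤ 0.05 and |log2FC| ≥ 0 by default; both thresholds exposed) in
every table — or in ≥ `min_datasets` tables when a k-of-n rule is wanted —
with the same sign of log2 fold change, which becomes its direction.
Significant genes with conflicting signs are excluded and reported, never
silently dropped. The operation is invariant to table order and row order,
and its output is a subset of every table's significant set. Intersection
happens on the source (model-organism) side; ortholog mapping to human
symbols follows, through a user-supplied two-column table (no live
database queries, for reproducibility). One-to-many mappings either fan
out (`keep_all`, the default) or drop the ambiguous source gene
(`drop_ambiguous`); two source genes mapping onto one target with opposite
directions drop that target with a report. Gene symbols are matched
case-insensitively throughout (mouse `Tap1` vs human `TAP1`), with
original spellings preserved for output.

The default padj threshold of 0.05 with no fold-change floor is a
placeholder for source analyses whose exact criteria are unknown; when a
DE table carries its own `significant` column, that call set overrides the
thresholds for that dataset.

## Association and survival statistics

Correlations (Pearson, or Spearman as Pearson on average ranks) use
pairwise-complete deletion, require n ≥ 3, and report two-sided p-values
from the t transform t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom
(scipy's implementation). Benjamini–Hochberg q-values are computed by the
standard step-up (statsmodels) and applied per explicitly declared family
of tests — one `associate` invocation or one pipeline association table is
one family; the package never pools p-values across runs.

Survival uses the dichotomized score: High (score > cutpoint) vs Low
(score ≤ cutpoint), with the boundary assigned to Low and cutpoint 0 by
default. Kaplan–Meier curves come from lifelines' product-limit fitter and
are exported as step tables with at-risk and event counts; the median
survival is the smallest time with Ŝ(t) ≤ 0.5 and is flagged undefined
when the curve never reaches 0.5. The two-group log-rank statistic is
accumulated directly over distinct event times (observed vs hypergeometric
expectation, with the standard variance term), because the result contract
exposes per-group observed/expected counts; it is cross-checked against
lifelines in the tests and its p-value is the asymptotic chi-square with
1 df — no permutation-exact variant is attempted. The Cox model for the
binary group indicator is fitted with statsmodels' PHReg, chosen because
it supports both Breslow (default here, for its simple closed-form oracle)
and Efron tie handling; confidence intervals are 95% Wald, exp(β̂ ± 1.96·se).
Complete separation (all events in one group with monotone risk sets)
makes the partial likelihood unbounded; fits with non-finite or extreme
β̂/se raise a ConvergenceError with a diagnostic rather than returning a
meaningless hazard ratio.

## Synthetic cohorts

The generator emulates only the structure the analysis assumes, with known
ground truth:

* latent activity a_j ~ Normal(0, 1) per sample;
* signature gene g: x_gj = d_g·β·a_j + ε, ε ~ Normal(0, σ), on the log2
  scale (β = `beta_sig`, default 1 log2 unit per activity unit;
  σ = `sigma_noise`, default 0.5);
* immune-module gene: x_gj = γ·a_j + ε with γ = `gamma_immune`
  (default −1, the immune-cold coupling);
* background genes: pure noise;
* survival: exponential event times with hazard
  λ_j = λ₀·exp(β_HR·1[a_j > median(a)]) (λ₀ = `baseline_hazard`,
  default 0.01/day; β_HR = `log_hr_high`, default 0.7), plus independent
  exponential censoring with rate μ = r/(1−r)·mean(λ) chosen so the
  expected censored fraction is approximately r = `censor_rate`
  (default 0.2).

The ground-truth High/Low split uses median(a) rather than 0 so the groups
are balanced regardless of sampling noise. All randomness flows from a
single seed through spawned substreams (activity, signature noise, immune
noise, background noise, survival, censoring), so identical configs give
bit-identical cohorts and resizing one gene block never perturbs another
block's draws. Default sizes — 200 samples, 50 + 50 signature genes, 50
immune genes, 1850 background genes — describe a mid-sized bulk cohort and
keep every end-to-end run in the seconds range.

Deliberately not modeled: negative-binomial count noise, batch effects,
tumor purity, correlated gene-gene structure beyond the single latent
factor, and informative censoring. Passing recovery tests on these cohorts
therefore shows that the pipeline's estimators are correct and calibrated
under the assumed generative structure, not that the biological signature
itself generalizes to any particular patient cohort.

## Pipeline

`run_pipeline` executes derive → map → preprocess → score → dichotomize →
associate → survival from one YAML/JSON config, recording every stage,
parameter, overlap count and warning in a machine-readable summary.
Outputs are deterministic given the config: reruns into clean directories
produce byte-identical TSVs, and logging verbosity never changes numeric
output. Centering mode is configurable: `all` centers every gene
(whole-transcriptome cohorts), `signature` centers only the signature
genes after subsetting (the mode matching per-signature-gene
median-centering of TPM/intensity data), `none` trusts the input scale.
Exit codes distinguish config errors (2), data/format errors (3) and
statistical degeneracies (4).

## Numerical choices

* Duplicate gene rows collapse by mean on the current scale, with a
  warning (deterministic and order-independent); all other invariant
  violations are rejected, not repaired.
* log2 transform uses a pseudocount (default 1 for raw counts/TPM; the
  appropriate value for already-shifted data is the caller's choice, so it
  is exposed rather than guessed).
* Median-centering is idempotent to 1e-12 and required (with an explicit
  override) before directional scoring.
* Scorer/oracle agreement is enforced to 1e-12 on small random instances
  in unit tests and 1e-9 in the acceptance suite; KM/log-rank oracles to
  1e-9.
* The acceptance problem sizes (200–500 samples, 2000 genes, 500 null
  replicates) were chosen to make every recovery property sharp while the
  whole suite runs in well under a minute per criterion.
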