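# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic cohorts do and do not emulate,
and the known limitations.

## Expression preprocessing

Counts are gene × sample UMI tallies. Library size is the total count over
all genes present in the matrix; CPM is `counts / libsize * 1e6` and scores
are computed on `log2(CPM + 1)` (a config switch to linear CPM exists for
sensitivity analysis). Per-gene Z-scores for heatmap export are computed
jointly across all samples (so groups share one color scale) with the
sample standard deviation (divisor n−1); zero-variance genes are set to
zero and flagged rather than dropped. Counts must be integral; a
`strict=False` reader option truncates fractional values (some quantifiers
split multimappers) with a warning.

The JESREC clinical score is a pure function of its printed scoring table:
3 points for bilateral involvement, 2 for nasal polyps, 2 for
ethmoid-dominant CT, and a blood-eosinophil tier of 0/4/8/10 points at
≤2%, (2,5]%, (5,10]%, >10%; the clinical-eligibility flag is `score ≥ 11`.
The separate tissue-eosinophilia requirement (≥70 cells/HPF) for a full
ECRS diagnosis is a metadata field for the caller, not part of the scoring
function.

## Scores

A gene-set score is the arithmetic mean of log2(CPM+1) over the set's genes
present in the data, resolved case-insensitively against the registry. When
genes are missing the score is the mean over the present subset as long as
coverage is ≥ 0.5 (configurable); below that the score is refused because a
mean over a small remnant no longer measures the module. A cytokine
interaction score is the ligand's expression times the mean expression of
its present receptor subunits. Both families use log2(CPM+1) by default;
the space is recorded alongside each output. An undetected ligand (all-zero
expression, as IL-25 typically is in nasal tissue) produces a well-defined
all-zero score carrying a zero-variance flag, and downstream association
models refuse zero-variance predictors explicitly.

The IL-33 and IL-25 receptor pairings ({IL1RL1, IL1RAP} and
{IL17RA, IL17RB}) follow canonical receptor biology and are overrideable in
a user registry; TSLP uses {CRLF2, IL7R}.

## Differential expression

The DE stage is a deliberately transparent DESeq2-style approximation,
validated against simulated truth rather than bit-matched to any external
tool:

- **Size factors** by median-of-ratios over genes positive in every sample,
  rescaled to geometric mean 1. If no gene is positive everywhere the stage
  stops and directs the user to a pseudo-reference fallback rather than
  silently changing estimator.
- **Dispersions** by per-gene method of moments on normalized counts,
  `α̂ = max(1e-8, (s² − μ)/μ²)`, with moments taken within design cells
  (≥2 samples) and combined with (n−1) weights so group mean shifts do not
  masquerade as dispersion. Raw estimates are shrunk 50/50 in log space
  toward a trend `α(μ) = a/μ + b` (a, b ≥ 0, non-negative least squares
  over genes). Estimates at the floor (zero or sub-Poisson variance) carry
  no information and stay at the floor. This is simpler than empirical-Bayes
  moderation but calibrates well at the simulated conditions (type-I error
  0.05 ± 0.02 at n = 6–8 per arm).
- **Wald test** per gene from an NB GLM with log link, design
  `intercept + group indicator`, offsets `log(size factor)`, dispersion held
  fixed; IRLS is vectorized across genes (shared design, per-gene weights)
  and fits are cross-checked against a reference GLM implementation in the
  tests. The Wald reference is normal (standard for NB GLMs; no t
  correction). Genes with all-zero counts in the tested samples, and
  non-converged or separated fits (one group all zero), are excluded from
  testing and from the BH denominator.
- **Calls** use strict inequalities: up if `padj < 0.05` and `log2FC > 1`,
  down if `padj < 0.05` and `log2FC < −1`, else ns. No independent
  filtering beyond the all-zero exclusion. Categorized DEG tables join
  calls against the registry (up = ◯, down = ▲).

The default contrast grid is the six pairwise comparisons among the four
arms. The design is unpaired two-group per contrast; the paired Pre/Post
structure is handled by the mixed models, not the DE stage.

## Mixed models

All inference runs through one random-intercept family
`y = Xβ + u_patient + e`, `u ~ N(0, σ²_u)`, `e ~ N(0, σ²_e)`, fit by REML.
Because there is a single grouping factor, the REML criterion is profiled
to one dimension in the variance ratio λ = σ²_u/σ²_e and minimized by
bounded scalar search (log-λ in [−14, 14]); the λ = 0 boundary is always
evaluated and preferred when it is as good as the interior optimum (the
profile is exactly flat when every patient contributes one observation, in
which case the model is deliberately collapsed to OLS).

- **Degrees of freedom**: Satterthwaite,
  `df = 2·Var(c'β̂)² / (∇f' Cov(θ̂) ∇f)` with θ = (σ²_u, σ²_e), the gradient
  by central finite differences and Cov(θ̂) from the finite-difference
  Hessian of the −2·REML criterion; df is clamped to [1, n−p] and boundary
  (singular) fits use the residual df exactly. If the information matrix is
  numerically singular the test falls back to a normal reference with a
  warning.
- **Group comparisons** use cell-means coding, so the fixed effects are the
  estimated marginal means. Tukey HSD p-values come from the
  studentized-range distribution with `q = |t|·√2` and the contrast's
  Satterthwaite df; at k = 2 this equals the unadjusted p exactly. A
  contrast is flagged *paired* when its two levels share patients; there is
  no separate paired t-test path — the random intercept carries the pairing.
- **Associations** (`y ~ x + (1 | patient)`) report the Nakagawa–Schielzeth
  marginal R² with σ²_fixed the variance (n−1 divisor) of the fixed-effect
  fitted values, conditional R² adding σ²_u, and the signed effect size
  `Rm = sign(slope)·√R²_marginal`. The default sample set is the
  cross-sectional arms (Ctrl, nonECRS, PreECRS) so each patient contributes
  once.
- **Recovery model**: `score ~ condition + b + condition:b + (1 | patient)`
  with condition ∈ {Pre = 0, Post = 1} and b the per-patient baseline
  cytokine interaction score, grand-mean-centered so the condition main
  effect is the mean recovery. The interaction coefficient equals the OLS
  slope of the per-patient difference on centered b in the balanced
  no-covariate case (tested to 1e-8). Clinical covariates enter
  z-standardized (their units are heterogeneous); zero-variance covariates
  are dropped with a warning, collinear designs raise, and missing values
  raise with the offending patients named (no imputation). Patient-level
  covariates are orthogonal to the within-patient interaction estimate in a
  balanced design, so adjustment moves p_interaction only through the df.

## Synthetic cohorts

The generator emulates a four-arm bulk UMI study: counts are NB with
per-gene dispersion α drawn log-uniformly from [0.01, 0.5] and log-uniform
library sizes in [5e5, 2e6] (conventional ranges for 3'-counting bulk
libraries, not measurements of any particular data set); per-sample means
are compositional, `L_s · 2^η / Σ 2^η`, so module shifts displace the rest
of the transcriptome as in real sequencing. Arm sizes default to 6 controls,
8 non-eosinophilic CRS and 9 paired Pre/Post patients. Patient random
intercepts (sd τ = 0.3 log2 units) attach to the scored modules — a global
per-patient shift would cancel in the compositional normalizer — and
per-patient correlated deviations (sd 1.0) move the IL-33 and TSLP
ligand/receptor blocks to create between-patient spread in baseline
interaction scores. Clinical covariates are drawn per arm from
surgical-cohort-like distributions, independent of all expression signal,
so they act as pure nuisance variables.

The recovery coupling is self-consistent: Pre counts are generated first,
the baseline IL-33 interaction score is computed from them through the
package's own scoring stage, and Post samples are then regenerated with an
extra `γ · (b − b̄)` shift on the cilia-master genes. The effect scenario's
γ = 0.015 was sized once from γ = 0 runs so the coupled term explains about
half of the per-patient recovery variance (measured sd of the centered
baseline score ≈ 16.6; sd of the recovery noise ≈ 0.25); at the study arm
size (9 paired patients) this gives the interaction test power of roughly
0.6–0.7, and the end-to-end qualitative checks therefore run at 50 paired
patients. The effect scenario also suppresses the ciliary/PCP modules
before treatment and elevates them after, keeps the EET-degradation genes
(DNASE1L3, PLAT, BPIFA1, BPIFB1) suppressed in both disease states, and
raises CCL26 and the IL-33 axis pre-treatment.

What the generator does **not** emulate: zero inflation, batch effects,
cell-type composition shifts, UMI saturation, gene–gene correlation beyond
the block structure above, or realistic gene-length/GC biases. Passing
tests therefore demonstrate correctness of the estimators under an NB
world with known truth — not robustness to every artifact of real tissue
data.

## Problem sizes used in the checks

The calibration checks run at 2000 genes (type-I error of the DE engine on
a null cohort; DEG threshold equivalence), 2000 score-level replicates for
the recovery model's type-I error at 9 paired patients, 500 replicates at
50 patients for coupling-estimate bias, and 20 simulated cohorts at 50
paired patients for the end-to-end qualitative pattern. These sizes give
Monte-Carlo error comfortably inside the asserted bands while keeping the
default test run quick.

## Known limitations

- The DE stage is not DESeq2: no empirical-Bayes dispersion moderation, no
  independent filtering, no LFC shrinkage. At very small n its dispersion
  estimates are noisier than moderated ones; the trend shrinkage mitigates
  but does not remove this.
- The mixed-model engine supports a single random intercept only — no
  random slopes, crossed factors or Kenward–Roger df.
- The built-in ciliogenesis and mucus registries are partial (the genes
  named in the main analyses); users with fuller curated lists should load
  them via the JSON/TSV registry interface.
- The JESREC scorer returns the clinical score only; combining it with
  tissue eosinophilia for a full diagnosis is left to the caller.
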