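# Methods

This note records the statistical models implemented in `sigrank`, the
defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical conventions that matter when comparing
against other software.

## Signature derivation

A two-group comparison over a log2 expression matrix. "ANOVA" with two
groups is one-way fixed-effects ANOVA, whose F statistic equals the
squared pooled-variance t; an unequal-variance (Welch) variant is
exposed via `welch=True` but is not the default. The fold change is the
difference of group means on the log2 scale, with group A the
lexicographically first label unless overridden — sign conventions are
logged on every run.

Multiple testing uses the Benjamini–Hochberg step-up
(`q_(i) = min_{j≥i} p_(j)·m/j`). The FDR method is fixed to BH as the
standard choice where only "FDR correction" is specified. A gene enters
the signature when `q < 0.05` **and** `|log2FC| > 1` (strictly greater:
"more than twofold" on the linear scale); both thresholds live in
`RunConfig`, never in code. Genes with zero within-group variance get
`p = 1` and a `degenerate` flag instead of aborting a genome-wide scan.
Probe-to-gene collapsing is out of scope: matrices are assumed
gene-level, complete (no missing values — parsers reject them) and
already log2; the pipeline never re-logs.

## Scoring, calibration, stratification

The signed signature score is `mean(z_up) − mean(z_down)` after z-scoring
each gene across samples (sample SD, ddof 1). This is a deliberate
design choice: it is the simplest signed score that makes
"signature-positive/negative" stratification well defined, it is
invariant to per-gene affine transforms, and flipping the up/down sets
negates it. Missing or zero-variance signature genes are skipped with a
warning; an empty side contributes zero.

Dichotomization rules: median split (default for survival
stratification), top/bottom quantile, or a fixed threshold. Ties at any
cut go to the negative class, so a "top 30%" rule never labels more than
30% of samples positive.

Pathway-activity calibration is a pure location shift: the offset is
`target − median(reference scores)` with target 0.15 by default, the
mutant-cohort anchor. Anchoring a single statistic determines only a
location adjustment, so no rescaling is applied, and ordering is
preserved by construction. "Low" activity means calibrated score below
the target. The Pten-low rule is a configurable bottom quantile (default
0.25); a quantile was chosen because only the resulting frequency, not
the rule, is reported in this literature.

## Survival machinery

*Kaplan–Meier*: standard product-limit estimator; censorings recorded at
an event time are kept in the risk set for that time's events.

*Two-sample tests*: weighted log-rank with weight `w_i = n_i` (total at
risk) is the Gehan–Breslow generalized Wilcoxon — the "Wilcoxon method"
of classical survival software — emphasizing early differences; `w_i = 1`
gives the log-rank. The statistic is referred to χ² with 1 df rather
than a permutation distribution; with no events at all the test returns
`p = 1` with a warning.

*Cox regression*: univariate partial likelihood maximized by
Newton–Raphson with analytic gradient and Hessian; Efron tie correction
by default (better for discrete recorded months), Breslow selectable.
Convergence at `|score| < 1e−9` or 50 iterations, steps damped to at
most 5. Monotone likelihood (risk-set separation) is detected when
`|β| > 15` during iteration and flagged rather than silently diverging.
SE is the inverse observed information; CIs and p-values are Wald.

*Limiting dilution*: single-hit Poisson model, binomial likelihood over
dose levels maximized over `log f` (bounded scalar minimization,
`xatol = 1e−12`). With a single dose level the MLE reduces to the closed
form `−ln(1 − k/n)/d`, which the optimizer reproduces. All-negative
tables return `f̂ = 0` with a one-sided 95% upper bound from the
likelihood ratio; all-positive tables return a lower bound only. The
default CI is Wald on `log f` (fast, standard for this assay class); a
profile-likelihood CI is available via `ci="profile"`.

## Random-signature null

Random signatures are drawn uniformly without replacement from the
matrix's genes with the real signature's composition (same up and down
counts). The universe excludes the real signature's genes by default so
no random draw partially overlaps it (overlap can be re-enabled). Each
signature — real and random — goes through the identical chain: signed
z-mean score, median split, Gehan–Wilcoxon p, Cox HR on the binary
label. Significance is gated on the Gehan–Wilcoxon p; both p and HR are
stored per signature so the gate can be switched. Ranks are reported
both among significant signatures (by descending HR) and among all
signatures, and the empirical p uses the `(1 + b)/(N + 1)` add-one
convention so it is never zero. A degenerate dichotomization yields
`(HR = NaN, p = 1)` and counts as non-significant.

All randomness is a seeded PRNG (`numpy.random.Generator`). This is a
deliberate deviation from drawing random gene sets from an external
physical-noise service: reproducibility of the null is worth more here
than non-determinism, and the null's validity depends only on uniform
sampling, which the PRNG provides.

## Dose–response and meta-analysis

The dose–response model is the four-parameter logistic
`y = bottom + (top − bottom)/(1 + (d/IC50)^hill)` — the field-standard
curve for MTT viability data, and deliberately the one standard
component in an otherwise bespoke chain. Fitting is bounded least
squares (`bottom ∈ [−0.2, 0.5]`, `top ∈ [0.5, 1.3]`, `hill ∈ [0.1, 10]`,
`IC50 ∈ [min dose/10, max dose·10]`) with a multi-start over log-spaced
IC50 initials plus a data-driven midpoint guess; the search stops early
once two starts agree on the optimum. Fits with the IC50 on a search
bound or an essentially flat response are flagged unreliable.

IC50s are log10-transformed before correlating with pathway activity —
raw micromolar values would let scale dominate the correlation; a raw
mode exists behind a flag. Per-experiment Pearson correlations are
pooled on the Fisher-z scale with `var(z) = 1/(n − 3)`; the default is
DerSimonian–Laird random effects (the default family of the standard
meta-analysis tooling), with fixed-effects pooling (`τ² = 0`) available.
Experiments with `n ≤ 3` are rejected by name since their z variance is
undefined.

## Synthetic generators

Every generator is bit-reproducible from its spec (including the seed)
and emits a truth table sufficient for parameter recovery.

* **Tumor matrix** (`TumorSimSpec`): 10,000 genes × 20+20 samples;
  per-gene baseline N(7, 1) on the log2 scale shared across groups;
  i.i.d. Gaussian noise with SD 0.5 (a typical post-normalization
  microarray residual scale); 7 up and 17 down planted genes shifted by
  ±2 log2 units (fourfold — comfortably above the twofold filter, as
  expected of a signature selected for large effects).
* **Cohort** (`CohortSimSpec`): n = 400 by default; balanced latent
  classes; signature genes shifted ±1 SD (loading 1.0) in positive
  patients; exponential event times with baseline hazard 0.02/month
  (median ~35 months for the low-risk class, a realistic metastasis-free
  survival scale) and planted HR 2.24; independent exponential censoring
  at 0.01/month (≈ one-quarter to one-third of patients censored).
  Exponential times are the simplest proportional-hazards-consistent
  generator — only the hazard ratio, not the baseline shape, matters to
  the implemented estimators. Balanced classes make the median split
  align with the latent truth, keeping recovery tests interpretable.
* **Reference cohort**: mutant scores N(0, 1), wild-type N(separation, 1)
  with separation 1.0 — the functional pathway scores higher.
* **Drug panels** (`PanelSimSpec`): 7 experiments × 6 lines; per line,
  (activity, log10 IC50) bivariate normal with correlation −0.70,
  activity N(0, 1), log10 IC50 centred on log10(0.2 μM) with SD 0.5
  (about a 10-fold IC50 range across lines); viabilities are the unit
  4PL (bottom 0, top 1, hill 1) plus Gaussian noise SD 0.05, clipped to
  the assay range [−0.1, 1.2]; 8 log-spaced doses from 0.001 to 10 μM.
* **Limiting dilution** (`LDSimSpec`): frequency 1/57, doses
  10/50/100/500 cells, 6 recipients per dose; outcomes Bernoulli with
  `p = 1 − e^{−fd}`.

What the generators do **not** emulate: probe- and batch-level array
artifacts, correlated gene–gene backgrounds, non-proportional hazards,
informative censoring, plate effects or systematic drift in viability
assays, and inter-animal heterogeneity in engraftment. Passing recovery
tests therefore demonstrates correctness of the estimators under their
own model assumptions, not robustness to the full messiness of real
cohorts and screens.

## Problem sizes and determinism

Recovery checks use 200 replicates for the Cox, limiting-dilution and
meta-analysis chains, and 1000 random signatures × 20 cohorts (n = 100)
for the whole-chain null calibration — sizes at which Monte-Carlo error
is a few percent of the quantities checked while a full run stays in the
minutes range on a single CPU. One master seed fans out to per-stage
31-bit child seeds via `numpy.random.SeedSequence.spawn`, so any stage
can be rerun in isolation with identical draws and the end-to-end report
is byte-identical under a fixed seed.

## Known limitations

Univariate Cox only (no covariate adjustment, time-varying effects or
competing risks); no moderated-variance (limma-style) differential
expression; calibration is location-only; the chi-square reference for
the two-sample tests is asymptotic and can be slightly off for very
small arms; the 4PL fit assumes viabilities roughly normalized to a
vehicle of 1.
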