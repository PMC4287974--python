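# sigrank

Statistical machinery for prognostic gene-signature studies in
transcriptomics, built around the analysis chain used to derive and
validate a 24-gene claudin-low triple-negative breast-cancer signature:

* **Signature derivation** — per-gene two-group ANOVA, Benjamini–Hochberg
  FDR, and a fold-change filter over a log2 expression matrix, yielding a
  *signed* signature (up- and down-regulated gene sets).
* **Signature scoring & stratification** — signed z-mean scores per
  sample, median or quantile dichotomization, and pathway-activity
  calibration that anchors a mutant-reference median at a target value.
* **Survival statistics, from scratch** — Kaplan–Meier product-limit
  curves, the Gehan–Breslow–Wilcoxon and log-rank tests, and univariate
  Cox proportional-hazards regression (Newton–Raphson on the partial
  likelihood, Efron or Breslow ties).
* **Composition-matched random-signature null** — N random signed
  signatures with the same up/down composition, each run through the
  identical score → dichotomize → survival chain, ranking the real
  signature and measuring the fraction of "significant" random ones.
* **Limiting-dilution assays** — single-hit Poisson maximum likelihood
  for tumor-initiating-cell frequency, `P(positive | dose d) = 1 − e^{−fd}`,
  with Wald or profile-likelihood intervals.
* **Dose–response & meta-analysis** — four-parameter logistic (4PL) IC50
  fitting with multi-start bounded least squares, per-experiment Pearson
  correlation of log10 IC50 with pathway activity, and Fisher-z
  DerSimonian–Laird random-effects pooling.

Seeded synthetic generators emulate every dataset class the chain
consumes (two-group tumor matrices with planted effects, cohorts with a
planted hazard ratio, mutant/wild-type reference cohorts, drug panels
with a planted activity–IC50 correlation, limiting-dilution outcomes), so
the whole pipeline is testable end to end without any external data.

## The models

**Cox model.** For a binary stratification `x ∈ {0,1}` the hazard is
`λ(t | x) = λ₀(t) e^{βx}`; `β` maximizes the partial likelihood and
`HR = e^β` is the hazard ratio between signature-positive and -negative
patients. The Gehan–Breslow–Wilcoxon statistic is the weighted log-rank
`(Σᵢ nᵢ(d_{Ai} − E_{Ai}))² / Σᵢ nᵢ²Vᵢ` over event times, referred to χ²₁.

**Single-hit model.** With TIC frequency `f`, a transplant of `d` cells
grows with probability `1 − e^{−fd}`; the binomial likelihood over dose
levels is maximized over `f` and reported as "1 in 1/f cells".

**4PL dose–response.** `y(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)`.

**Meta-analysis.** Per experiment `z = atanh(r)`, `var(z) = 1/(n−3)`;
DerSimonian–Laird `τ²` inflates the weights, and the pooled `z` is
back-transformed with `tanh`.

## Worked example

```python
from sigrank import CoxPH, limiting_dilution_mle
from sigrank.core_io import SignedSignature
from sigrank.scoring import score_signature, dichotomize
from sigrank.synthetic_data import CohortSimSpec, simulate_cohort

matrix, cohort, truth = simulate_cohort(CohortSimSpec(rng_seed=7))
sig = SignedSignature("WCLS-like",
                      {f"sig_up{i}" for i in range(7)},
                      {f"sig_dn{i}" for i in range(17)})
labels = dichotomize(score_signature(matrix, sig), "median").label
print(CoxPH(cohort.time, cohort.event, labels).fit().summary())
```

```
Univariate Cox proportional hazards
===================================
n = 400, events = 299, ties = efron
beta (log HR) =  0.8842  (SE 0.1228)
HR            =  2.4209  [95% CI 1.9029, 3.0800]
Wald p        = 6.118e-13
converged = True (5 iterations)
```

The cohort generator planted a hazard ratio of 2.24 between latent
signature classes; the median split of the signed z-mean score recovers a
hazard ratio of 2.42 with a confidence interval covering the truth — the
signature stratifies the cohort into high- and low-risk halves.

```python
print(limiting_dilution_mle([10, 50, 100, 500], [6, 6, 6, 6], [1, 4, 5, 6]).summary())
```

```
Single-hit Poisson limiting-dilution estimate
=============================================
TIC frequency  = 0.0195309  (1/51.2 cells)
95% CI (freq)  = [0.00993174, 0.0384079]
```

One tumor-initiating cell per ~51 cells transplanted, with a 95% interval
of roughly 1/26 to 1/101.

Every stage is also a CLI subcommand (`sigrank simulate`, `derive`,
`score`, `calibrate`, `survive`, `nullrank`, `ldassay`, `drugfit`), and

```bash
sigrank reproduce --seed 7 --out-dir report/
```

runs the full seeded chain — fixture generation, 24-gene signature
recovery, survival stratification, the 1000-signature random null,
limiting dilution and the IC50 meta-analysis — and writes a deterministic
`report.json`.

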