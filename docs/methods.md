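# Methods

This note documents the statistical model implemented by `cogaging`, the
choices made where the design was genuinely open, and what the synthetic
cohort generator does and does not emulate.

## Scientific setting

Long-term cancer survivors may age cognitively differently from peers
without a cancer history. Repeated neuropsychological testing is the
obvious study design, but it is confounded by practice effects — people
improve on a test battery simply from having seen it before — and by
selective attrition. The approach implemented here separates the two
sources of information inside one model: a participant's **first
assessment** (the person-level intercept, the *cross-sectional* score) is
free of practice effects and, compared across enrollment ages, proxies the
aging trajectory; the **repeated assessments** (the person-level slope
over study months, the *longitudinal* score) absorb practice effects and
are analyzed simultaneously rather than discarded.

The pipeline covers four stages: neuropsychological domain scoring, a
deficit-accumulation frailty index, a Bayesian varying-intercepts/
varying-slopes growth-curve model, and a post-hoc cohort-gap analysis
over age.

## Domain scoring

Two composites are formed from a 16-test battery: **APE** (attention,
processing speed, executive function; 7 tests) and **LM** (learning and
memory; 9 tests). Per test:

1. **Normality check.** A sample is flagged non-normal when its absolute
   skewness exceeds a threshold (default 1.0). A skewness criterion was
   chosen over a significance test (Shapiro–Wilk and relatives) because
   significance scales with sample size: at n ≈ 500 a test rejects for
   trivial departures, while the transform decision should depend on the
   shape alone. The threshold is configurable.
2. **Box–Cox.** Flagged tests are power-transformed. The exponent is
   chosen by profile-likelihood grid search over λ ∈ [−3, 3] in steps of
   0.01 (scipy's `boxcox_llf` supplies the likelihood); when any value is
   ≤ 0 a shift of 1 − min is applied first so the minimum becomes 1. The
   grid, rather than a continuous optimizer, makes the fitted λ
   deterministic and platform-stable; the 0.01 step is far below any
   practically meaningful difference in the transform.
3. **Standardization.** z = (transformed value − reference mean) /
   reference SD, where the reference moments are computed from **baseline
   (month 0) control visits only** and then applied unchanged to every
   visit of every participant. The reference population defines the
   scale; fitting it on controls at baseline keeps group effects and
   practice effects out of the transform. Timed tests (higher = worse)
   have their z negated so larger is always better — the standard
   neuropsychology convention.
4. **Composites.** The domain score is the mean of available member-test
   z-scores, reported only when at least half the domain's tests (rounded
   up) are present.

Consequences worth knowing: because the composite is a mean of
noisy unit-SD test z-scores, its own SD is below 1 and population-level
coefficients estimated from composites are attenuated relative to the
latent domain scale (the acceptance run reports both scales side by
side). This mirrors how composite scoring behaves on real batteries.

## Deficit-accumulation frailty index (DAFI)

Up to 44 ordinal indicators, each coded 0 (absent), 1 (intermediate) or 2
(most adverse risk), covering functional status, comorbidity, depression,
anxiety and fatigue. The index is

    DAFI = Σ codes / (2 × n assessed),

in [0, 1]. A missing indicator leaves both numerator and denominator.
The score is valid only when ≥ 35 indicators were assessed. Categories:
robust < 0.2 ≤ pre-frail < 0.35 ≤ frail. The boundary placement uses
half-open intervals, consistent with the unambiguous robust and frail
definitions. Indicators excluded by design (e.g. self-reported cognition,
the cancer history that defines the cohorts) never enter the score.
Mapping raw instruments onto 0/1/2 codes is the caller's responsibility
via a schema; only the index arithmetic is in scope here. All 44 items
are treated as uniformly 0–2 coded, which is what the index formula
implies.

## The growth-curve model

For participant *i* at visit *t* (m = months since baseline, 0/8/16/24):

    y_it = α_i + β_i·m_it + ε_it,              ε ~ N(0, σ_ε²)
    α_i  = γ00 + γ01·c_i + γ02·c_i² + S_i(γ03 + γ04·c_i + γ05·c_i²) + u_i
    β_i  = γ10 + γ11·S_i + Σ_{k=2..4} (γ12.k + γ13.k·S_i)·[Q_i = k] + v_i
    (u_i, v_i) ~ N₂(0, Ω),   Ω = [[σ_α², ρσ_ασ_β], [ρσ_ασ_β, σ_β²]]

with c_i = enrollment age − center (default: sample mean age rounded to
0.1; 72.5 in the reference configuration), S_i the survivor indicator and
Q_i the baseline age quartile with default bins 60–68 / 69–72 / 73–76 /
77–89 (youngest = reference). Slopes vary by categorical age cohort
rather than continuous age so that time is not counted twice, and γ10 is
per raw month (no rescaling). The correlation ρ captures whether people
who score higher at enrollment also gain more from practice.

### Inference

No probabilistic-programming backend is used; the posterior is sampled by
a **blocked Gibbs sampler** written for exactly this model:

* **Fixed effects γ** are drawn from their Gaussian full conditional with
  the random effects *integrated out analytically* (Woodbury identity on
  the per-person 2×2 blocks). Collapsing this block removes the strong
  γ–random-effect autocorrelation that a naive sampler exhibits.
* **Random effects (u_i, v_i)** are drawn per person from closed-form
  bivariate normal conditionals.
* **Ω** is drawn from its Inverse-Wishart conditional (2×2 Bartlett
  construction, validated against `scipy.stats.invwishart`).
* **σ_ε²** is drawn from its Inverse-Gamma conditional.

Priors are conjugate and weakly informative, autoscaled in the spirit of
`rstanarm` defaults: γ_j ~ Normal(0, 2.5·sd(y)/sd(x_j)) (2.5·sd(y) for
the intercept and for degenerate columns), σ_ε² ~ InvGamma(1, sd(y)²/2),
Ω ~ InvWishart(ν₀ = 3, 0.01·diag(sd(y)², (sd(y)/month span)²)). A
half-Normal/LKJ formulation would be the usual choice under an HMC
backend; the conjugate forms are equivalent in spirit (proper, weak,
data-dominated at study size) and admit exact Gibbs steps. All
hyperparameters can be overridden.

Sampler presets: `test` (4 chains × 2,000 iterations, 500 warmup) for
desk-scale work, and `paper` (4 × 60,000, 10,000 warmup, thin 5) for
production runs. Convergence is monitored by the classic split-chain
potential-scale-reduction statistic with threshold R̂ ≤ 1.01; a failed
check is carried as an explicit warning in the result, never silently.
Two behaviors of the desk preset are expected and documented rather than
hidden: (i) the variance block (σ_β, ρ) mixes slowly because individual
slopes are barely identified with four visits (per-person OLS slope error
≈ σ_ε/√320 ≈ 0.011 against σ_β ≈ 0.004), so its R̂ typically sits in
1.02–1.10 at desk scale while the fixed effects converge; (ii) for the
same reason the posterior for ρ is wide and its magnitude is poorly
pinned (its sign is recoverable; interval estimates are honest about the
rest). The `paper` preset (~1 minute per fit on one CPU) brings R̂ down.

Degenerate inputs are handled explicitly: single-visit data leave the
slope block at its prior and the fit carries a flag; a constant-age
sample zeroes the age columns, which then revert to their priors (also
flagged); participants with missing age or group are reported in a
rejects table, not silently dropped.

**HDI.** 95% highest-density intervals are computed as the shortest
contiguous window containing ⌈0.95·n⌉ sorted draws, ties broken toward
the lowest start (cross-checked against `arviz.hdi` in the tests).

**DAFI as outcome.** The same Gaussian model is applied to the index on
its raw [0, 1] scale. This is a Gaussian approximation to a bounded
outcome; it is adequate for the observed index range (roughly 0.05–0.5)
but would misbehave near the boundaries.

## Post-hoc analysis

* **Per-decade effects**: 10 × the per-year linear age coefficient
  (e.g. γ01 = −0.047/year → 0.47 z-scores of decline per decade).
* **Gap curve**: per posterior draw and age a, Δ(a) = γ03 + γ04·(a−c) +
  γ05·(a−c)²; the band is the per-age HDI of the draw-level Δ(a)
  distribution, computed from joint draws (not from parameter-wise
  intervals) so posterior correlations among the three coefficients are
  respected.
* **Null-crossing age**: scanning the default 60–89 grid (step 0.1 year)
  in ascending age, the first age where the band contains zero — the age
  beyond which the cohort difference stops being credibly non-zero. If
  the band contains zero from the grid start, the start age is returned
  with an explicit flag; if it never does, no crossing is reported. The
  full boolean significance vector is retained so window-type patterns
  (a gap significant only between two ages) are recoverable as interval
  endpoints.
* **Trajectory panels**: per outcome, cross-sectional quadratic curves by
  cohort with credible bands, per-quartile longitudinal segments
  (intercept at the quartile's mean age, slope over months 0–24), and the
  gap curve with its crossing annotation. Empty quartiles are omitted
  with a log notice.

## Synthetic cohort generator

The generator exists so every downstream stage is testable against known
ground truth; its defaults emulate the reference study's structure: 328
survivors and 158 controls, enrollment ages truncated-normal on [60, 89]
with mean 72.5 and SD 5.8, visits at months 0/8/16/24, fixed effects set
to the reference analysis' posterior means for APE and LM, random-effect
SDs (0.60/0.004 APE, 0.64/0.005 LM), correlations (0.16, 0.27) and
residual SDs (0.194, 0.361).

Generation follows the model equations exactly, then adds realism the
model does not assume:

* **Raw tests** are per-test affine maps of the domain value plus noise
  skewed through a sinh-arcsinh tilt, `sd·sinh(asinh(Z) + s)`; s = 0 is
  exactly Gaussian. Timed tests get right-skewed noise so the Box–Cox
  stage has genuine work to do; offsets/loadings use plausible raw-score
  scales (e.g. Trail Making B ≈ 95 ± 25 s).
* **Indicators** are independent per-item cumulative-logit draws whose
  adverse-code probability rises with age (+0.045/year on the log-odds),
  is elevated in survivors by a log-odds offset that declines with age
  (0.9 at 60, ~0 by 78 — so cohort gaps are widest young, as the frailty
  literature reports), and drifts up slowly over study months. Between-
  item dependence is deliberately out of scope. A 2% per-item missing
  rate exercises the missing-item rule.
* **Dropout** is monotone with a per-visit hazard of 0.08 (≈ 22%
  cumulative attrition over two years, typical of older-adult cohorts);
  baseline is always observed.

All randomness flows from one root `numpy` `SeedSequence`, so a config +
seed pair reproduces the cohort byte-for-byte.

What the generator does **not** emulate — hence what passing tests do not
show about real data: real instruments' floor/ceiling effects and
discreteness, correlated indicator batteries, informative (outcome-
dependent) dropout, visit-date jitter around the 8-month schedule, and
cohort effects other than the modeled age trends. Parameter-recovery
results here certify the estimator, not the untestable assumptions.

## Problem sizes and numerical choices

Desk-scale defaults were chosen so a full end-to-end run (486
participants, three outcomes) completes in about two minutes on one CPU:
the Gibbs sampler costs ~0.3 ms per iteration at that size. The
parameter-recovery suite uses 20 replicates of 300 participants with the
`test` preset and checks 95% HDI coverage of every generating fixed
effect at ≥ 16/20 (the binomial 95% band around a true 0.95 coverage).
Numerical guards: σ_ε² floored at 1e−12; Cholesky of the 2×2 conditional
covariance floored to keep L22 real under extreme collinearity; Box–Cox
applied out-of-sample maps non-positive shifted values to missing rather
than producing complex powers.

## Known limitations

* ρ and σ_β are weakly identified with four visits per person; treat
  their point estimates with the width of their intervals in mind.
* The Gaussian treatment of the DAFI outcome ignores its boundedness.
* The normality screen is a skewness rule only; heavy-tailed symmetric
  scores will not trigger a transform.
* Quartile bins are fixed at baseline; a participant aging across a bin
  boundary during follow-up stays in their baseline cohort by design.
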