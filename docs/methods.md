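# Methods

## Model

Each eye's MD series is modelled as a noisy linear trend,

    y_ij ~ Normal(a_i + b_i * t_ij, sigma_e^2),   t_i1 = 0 at the first test,

with random effects drawn from sign-reversed exponential populations:

    b_i = mu_b - Xb_i,  Xb_i ~ Exponential(lam_b)        (slopes, dB/year)
    a_i = mu_a - Xa_i,  Xa_i ~ Exponential(lam_a)        (intercepts, dB)

The defining idea is that the Gaussian half of the exGaussian distribution
of *observed* slopes is not an extra random effect but the OLS estimation
noise itself: conditional on the latents, the OLS slope of eye *i* is
`b_i + e_i` with `e_i ~ Normal(0, sigma_e^2 / S_tt,i)`, `S_tt,i = sum_j
(t_ij - t_i_bar)^2`, so marginally the observed slopes follow an exGaussian
with rate `lam_b`, Gaussian mean `mu_b` and per-eye Gaussian variance
`sigma_e^2 / S_tt,i`. Consequences used throughout:

* **Interpretation.** `-1/lam_b` is the mean *true* rate of progression;
  `mu_b` absorbs any systematic positive offset on observed slopes — in
  practice the perimetric learning effect; `mu_b - 1/lam_b` is the
  population mean a Gaussian random-effects model estimates (biased toward
  zero progression by learning).
* **Parameter parity.** The between-subject slope variance is the derived
  quantity `1/lam_b^2 + mean_i(sigma_e^2 / S_tt,i)` (the summary reported
  as "Gaussian variance"); no free variance parameter exists, so the model
  has five population parameters (`lam_a, mu_a, lam_b, mu_b, sigma_e`),
  the same count as the reference Gaussian-LMM
  (`mu_a, tau_a, mu_b, tau_b, sigma_e`).
* **Heterogeneous schedules.** Eyes with shorter or sparser follow-up have
  larger implied Gaussian variance automatically; each observed slope is
  effectively drawn from its own exGaussian while sharing `lam_b, mu_b`.

An alternative formulation adds an explicit per-eye Gaussian slope
component with variance equal to the squared expected SE *on top of* the
response noise. We rejected it: it double-counts the estimation noise (the
marginal observed-slope variance becomes `1/lam^2 + 2 SE^2`), and on data
whose observed slopes are exponential-plus-single-noise it biases the
exponential mean toward zero by about 0.05 dB/year (verified against an
unbiased marginal maximum-likelihood cross-check). Only the formulation
used here reproduces the identities the model is built around — Gaussian
variance = average squared slope SE, parameter parity, and the empirical
OLS slope distribution matching the fitted exGaussian.

The intercept side is an acknowledged approximation: the true baseline
damage is (rate × disease duration), a product distribution that is not
exactly exponential. The model uses the exponential approximation with the
expected intercept SE `sigma_e * sqrt(1/n_i + t_i_bar^2 / S_tt,i)` as the
Gaussian SD. See "Limitations".

## Priors

Default-weak: `lam ~ Gamma(shape 1, rate 0.1)` for both rates;
`mu_b ~ Normal(0, 1 dB/year)`; `mu_a ~ Normal(0, 2 dB)`;
`sigma_e ~ Half-Normal(5 dB)`; in the Gaussian-LMM,
`tau_b ~ Half-Normal(2 dB/year)`, `tau_a ~ Half-Normal(10 dB)`.
The `practically-uninformative` variant widens every scale tenfold and is
the default for WAIC comparisons, so both models receive comparable prior
information. All priors are proper.

## Sampler

A blocked Gibbs sampler in numpy/scipy:

1. `(a_i, b_i)` given populations: the exponential prior is an exponential
   tilt of the Gaussian likelihood, so each conditional is a one-sided
   truncated normal; the pair is alternated twice per sweep to handle the
   intercept–slope likelihood correlation. Truncated-normal draws use the
   inverse-CDF in survival space (accurate to z ≈ 30) with an
   exponential-tail approximation beyond.
2. `lam` given latents: conjugate Gamma. `(mu_a, mu_b)` given latents:
   joint conjugate bivariate normal.
3. A **ridge translation move** (mu and all latents X shifted together,
   which leaves every `a_i`/`b_i` and hence the likelihood invariant)
   repeated several times per sweep; it mixes the decomposition between
   the exponential and Gaussian components, the model's one slow direction.
4. `sigma_e` (and the Gaussian-LMM `tau`s): random-walk Metropolis on the
   log scale, step size adapted toward ~35% acceptance during warmup only.

Defaults: 2 chains, 1500 warmup sweeps, 1000 kept draws per chain with
thinning 16 (the decomposition ridge has an integrated autocorrelation time
of tens of sweeps; thinning keeps memory for the pointwise log-likelihood
bounded while delivering bulk ESS well above the 400-per-parameter floor).
Convergence contract: split-R-hat < 1.01 and ESS >= 400 for every
population parameter, computed with arviz; violations raise (or warn, with
`strict=False`) carrying the diagnostics. A fit of 1000 eyes / ~12,500
tests takes ~20 s on one CPU core.

Per-draw pointwise log-likelihoods (conditional on the random effects, the
standard choice for this model class) feed WAIC on the deviance scale with
the sample-variance (ddof = 1) penalty, matching the R `loo` convention;
paired comparisons use the pointwise differences for the SE.

## Synthetic cohorts

The generator emulates a real-world glaucoma perimetry database; defaults
are the reference cohort's descriptors and the fitted population values:

| parameter | default | meaning |
|---|---|---|
| `lam_true` | 1/0.377 (dB/yr)^-1 | exponential true rates, mean −0.377 |
| `learn_mu` | +0.094 dB/yr | OLS-slope offset induced by learning |
| `learn_span_tests` | 7 | learning deficit reaches zero at test 7 |
| `sigma_e_mean` | 1.97 dB | residual SD (0.94 = test-retest preset) |
| `n_tests_median/IQR` | 12 (11–15) | lognormal, truncated at ≥ 10 |
| `followup_median/IQR` | 11 (8–13) y | truncated normal, ≥ 4 y |
| `duration_shape/mean` | 1 / 17 y | Gamma time from onset to first test |
| `healthy_md_sd` | 0 dB | inter-subject healthy-MD spread |

Learning is an additive early-test MD deficit decaying linearly to zero at
test `learn_span_tests`; its amplitude is calibrated per eye so the induced
OLS slope offset equals `learn_mu` exactly for that eye's schedule (about
1 dB at the first test under the default schedule). Baseline damage is
(true rate × Gamma disease duration), centred near −6.4 dB. The duration
shape defaults to 1 — an exponential waiting time, i.e. constant hazard of
first presentation. Sensitivity: heavier-shouldered duration distributions
(e.g. shape 2) make the intercept product distribution depart further from
the model's exponential approximation and leak a bias of roughly +0.02
dB/year into the learning mean (and the opposite into the exponential
mean); the real cohort's behaviour, where the intercept model choice had
minimal effect on the slope estimates, corresponds to the shape-1 regime.

What the generator does **not** emulate: pointwise (52-location) fields,
perimetric floor effects, MD-dependent variability, treatment changes, or
the empirical distribution of inter-test intervals (schedules are evenly
spaced with optional jitter; only the count/follow-up summaries are
matched). Passing recovery tests on these cohorts therefore demonstrates
correctness of the estimation machinery under the model's own assumptions
plus realistic schedule heterogeneity and learning artifacts — not
robustness to every feature of clinical data.

## Eligibility and severity

The clinical filters are reproduced exactly: tests with false-positive
rate ≥ 15% are dropped first; an eye is eligible with ≥ 10 surviving tests
spanning ≥ 4 years and MD strictly worse than −2 dB in ≥ 2 tests; times are
re-anchored to the first surviving test. Severity uses the mean of the
first two MD values: early ≥ −6 dB > moderate ≥ −12 dB > advanced. The
severity-stratified fit runs the identical sampler per group from one
spawned seed sequence (equivalent to independent fits, with aligned draws
so pairwise differences and probability-of-direction p values — `2 x (1 -
pd)`, floored at 2/n_draws — are computed draw-wise).

## Trials and power

A simulated two-arm trial samples 2N subjects without replacement from a
reference summary table (their baseline MD becomes the intercept and,
optionally, their residual SE the noise SD), draws true rates from
`Exponential(lam)` in the control arm and `Exponential(lam/(1-E))` in the
treatment arm — a neuroprotective effect E is a proportional slowing — and
simulates MD at the schedule times (default: 8 visits evenly over 2 years
with same-day retests, 16 tests; the exact visit months of the historical
trial design this mimics are not published, so the schedule is a plain
config list).

* **Method 1** (mixed-model interaction test): for these balanced
  complete shared-schedule designs the REML solution is closed-form — the
  fixed effects are the per-arm means of per-subject OLS coefficients for
  *any* random-effect covariance of the form `sigma^2 I + W G W'`, the
  residual variance comes from the pooled within-subject RSS, and the
  interaction SE from the pooled between-subject coefficient covariance.
  When the implied G leaves the positive-semidefinite cone (rare with
  realistic baseline spread, e.g. ~0.1% of simulations at N = 250/arm) the
  simulation falls back to numeric constrained REML. The reference
  distribution is t with 2N − 2 df — numerically the Satterthwaite value
  for this design (validated against lme4/lmerTest to five decimals in the
  test suite; statsmodels' MixedLM reproduces the estimate exactly but its
  optimizer leaves a few percent of slack on the SE).
* **Method 2**: Welch's unequal-variance t-test on per-subject OLS slopes.
* **Analytic power**: arm moments of the observed slopes are
  `mean_c = -1/lam`, `var_c = 1/lam^2 + v`; `mean_t = -(1-E)/lam`,
  `var_t = (1-E)^2/lam^2 + v`, with `v = sigma_e^2 / S_tt` of the schedule;
  power is the two-sided noncentral-t tail with Welch–Satterthwaite df and
  noncentrality `(E/lam) / sqrt((var_c+var_t)/N)`. At E = 0 this returns
  exactly alpha. A learning offset common to both arms cancels from the
  mean difference and so from the power — only the difference in true
  rates matters.

Monte-Carlo grids are vectorized (full MD series simulated in chunks, OLS
by projection), seeded per cell from a spawned sequence, and report the
binomial SE `sqrt(p(1-p)/n_sims)` with 1.96-SE intervals. The analytic
curve tracks simulation to within a few percentage points at 1000
simulations per cell; the residual gap is dominated by Monte-Carlo noise
plus the normal-theory approximation to the skewed slope distribution
(about 1 point at mid power).

## Numerical choices

* exGaussian pdf/cdf evaluated via `log_ndtr` (log-space complementary
  normal) so large `lam * sigma` cannot overflow; `sigma = 0` is an exact
  reflected-exponential branch.
* OLS residual SE uses the n − 2 denominator (unbiased for the variance);
  eyes need ≥ 3 tests and a non-degenerate schedule.
* The one-sample KS test evaluates D at both limits of every jump and uses
  the asymptotic Kolmogorov p value, with no correction for estimated
  parameters — a deliberate fidelity choice to the analysis it mirrors.
* Trimming re-anchors t = 0 at each eye's new first test so intercept SEs
  stay defined; trim level 0 reproduces the plain fit draw-for-draw under
  the same seed.
* Sampler starts: per-eye OLS values; method-of-moments for `lam`/`mu`
  (exponential variance = observed slope variance minus mean squared SE,
  floored); chain-specific jitter for overdispersed initialization.

## Limitations

* Per-eye *true* rates are not identifiable — any (exponential, Gaussian)
  pair summing to the observed slope is equally plausible — so the package
  reports population parameters and shrinkage-aware posterior slopes, never
  a per-eye "denoised" rate.
* The intercept model is an exponential approximation to a product
  distribution; with the default generator it contributes a residual bias
  of roughly +0.01 dB/year to the learning mean at n = 1000 (well inside
  the posterior spread, but visible when averaging many replicates).
* Noise is homoscedastic within eye and independent of damage level;
  test-retest data suggest variability grows with damage. The 0.94 dB
  test-retest preset bounds the optimistic end.
* WAIC is conditional on the random effects; marginal-likelihood model
  comparison is out of scope.
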