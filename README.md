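# vfprog

Hierarchical exGaussian modelling of visual-field progression rates, with
clinical-trial power tools.

## The problem

Glaucoma is monitored with standard automated perimetry; the mean deviation
(MD, in dB) summarizes each visual-field test, and the **rate of
progression** (RoP) of an eye is the slope of MD over time in dB/year.
Because the disease only worsens, the *true* RoP of every eye is ≤ 0 — yet
slopes estimated by linear regression form a two-tailed, negatively skewed
distribution with plenty of positive values, because measurement noise and
the perimetric **learning effect** (patients perform better over their first
several tests) contaminate the estimates. Population studies and
neuroprotection trials both need the *denoised* distribution.

## The model

`vfprog` fits a Bayesian hierarchical linear mixed model (LMM) in which the
random slope of eye *i* is

```
b_i = μ_b − X_i,          X_i ~ Exponential(λ_b)
y_ij ~ Normal(a_i + b_i t_ij, σ_e²)
```

so each observed (OLS-estimated) slope is the sum of a reflected-exponential
"true" rate, a learning offset μ_b, and Gaussian estimation noise whose SD
is the schedule-determined standard error σ_e/√Σ(t−t̄)² — an **exGaussian**
(exponentially modified Gaussian) distribution, with the exponential tail
pointing toward fast progression. Intercepts get the same treatment with
the expected intercept SE. Key consequences:

* the between-subject variance of observed slopes is `1/λ_b² + mean(σ_e²/S_tt)`
  — no free random-effect variance, so the model estimates the same number
  of population parameters as a standard Gaussian-LMM;
* `−1/λ_b` is the mean **true** RoP, `μ_b` isolates the learning bias, and
  `μ_b − 1/λ_b` is the (biased) observed mean a Gaussian-LMM reports;
* a neuroprotective effect E is a clean proportional slowing: divide λ_b by
  (1 − E).

Inference is by a blocked Gibbs sampler (conjugate updates, truncated-normal
latents, adaptive Metropolis for scales, a ridge-translation move for the
exponential/Gaussian decomposition), with split-R̂ / effective-sample-size
diagnostics via `arviz` and pointwise log-likelihoods retained for WAIC
model comparison. A synthetic-cohort generator reproduces the statistical
structure of a real-world perimetry database (variable schedules, learning
deficits fading by the 7th test, exponential-in-duration baseline damage),
and a trial module simulates two-arm RCTs (mixed-model interaction test and
Welch t-test on slopes) alongside a closed-form noncentral-t power
approximation.

## Worked example

```python
from vfprog import (GeneratorConfig, MCMCConfig, generate_cohort,
                    fit_exgauss_lmm, fit_gaussian_lmm, compare_waic,
                    analytic_power, ukgts_schedule)

cohort, truth = generate_cohort(GeneratorConfig(n_eyes=400, seed=7))
print(f"true mean RoP of the generated cohort: {truth.true_slope.mean():.3f}")

exg = fit_exgauss_lmm(cohort, mcmc=MCMCConfig(seed=1))
gau = fit_gaussian_lmm(cohort, mcmc=MCMCConfig(seed=2))
for name in ("exp_mean_slope", "mu_slope", "sample_mean_slope"):
    lo, hi = exg.ci(name)
    print(f"{name:18s} {exg.mean(name):+.3f} [{lo:+.3f}, {hi:+.3f}]")
print(f"Gaussian-LMM mean  {gau.mean('mu_slope'):+.3f}")
cmp = compare_waic(exg.pointwise_loglik(), gau.pointwise_loglik())
print(f"WAIC difference: {cmp.difference:.1f} [SE {cmp.se_difference:.1f}]")
print(f"power at E=30%, N=250/arm: "
      f"{analytic_power(1/0.38, 0.3, 1.97, ukgts_schedule(), 250):.3f}")
```

prints

```
true mean RoP of the generated cohort: -0.366
exp_mean_slope     -0.368 [-0.415, -0.325]
mu_slope           +0.096 [+0.064, +0.129]
sample_mean_slope  -0.272 [-0.313, -0.233]
Gaussian-LMM mean  -0.273
WAIC difference: -84.1 [SE 19.4]
power at E=30%, N=250/arm: 0.341
```

The exGaussian fit recovers the generating true mean (−0.366) and the
learning offset (+0.094) separately; the Gaussian-LMM can only report their
sum (−0.273), i.e. a mean rate biased upward by learning. The negative WAIC
difference (beyond 2 SE) says the skewed model predicts the data better.
The last line is the closed-form power of a 2-year, 16-test trial with 250
eyes per arm against a 30% proportional treatment effect.

The same workflows are scriptable from the shell — `vfprog simulate`,
`filter`, `fit`, `compare`, `trim`, `groups`, `power`, `power-analytic` —
each writing a JSON manifest (config hash, seed, versions, diagnostics) so
any artifact can be regenerated from its manifest alone. See
`docs/methods.md` for the model assumptions, priors and numerical choices.

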