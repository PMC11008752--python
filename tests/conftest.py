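import numpy as np
import pytest

from vfprog import (
    ExGaussParams,
    GeneratorConfig,
    MCMCConfig,
    fit_exgauss_lmm,
    fit_gaussian_lmm,
    generate_cohort,
    summarize_cohort,
)

# population parameters of the reference clinical fit: exponential mean
# -0.377 dB/year, learning offset +0.094 dB/year, residual SD 1.97 dB
TRUE_EXP_MEAN = -0.377
TRUE_LEARN_MU = 0.094
TRUE_SIGMA_E = 1.97


@pytest.fixture(scope="session")
def table1_params():
    return ExGaussParams(lam=1.0 / 0.377, mu=0.094, sigma=np.sqrt(0.037))


@pytest.fixture(scope="session")
def medium_cohort():
    """500-eye cohort under the default (clinical-like) generator settings."""
    cohort, truth = generate_cohort(GeneratorConfig(n_eyes=500, seed=7101))
    return cohort, truth


@pytest.fixture(scope="session")
def medium_fits(medium_cohort):
    """Both hierarchical fits of the medium cohort, log-likelihoods retained.

    Draw counts are reduced relative to the defaults to keep the suite
    quick; diagnostics are still checked (with a correspondingly lower
    effective-sample-size floor).
    """
    cohort, truth = medium_cohort
    exg = fit_exgauss_lmm(cohort, mcmc=MCMCConfig(
        warmup=1000, draws=600, thin=8, seed=71, min_ess=200, rhat_max=1.02))
    gau = fit_gaussian_lmm(cohort, mcmc=MCMCConfig(
        warmup=1000, draws=600, thin=8, seed=72, min_ess=200, rhat_max=1.02))
    return truth, exg, gau


@pytest.fixture(scope="session")
def reference_summaries():
    """Per-eye OLS summaries of a synthetic cohort, used as the pool of
    baseline MDs / noise levels for trial simulation."""
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=1200, seed=2205))
    return summarize_cohort(cohort)
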