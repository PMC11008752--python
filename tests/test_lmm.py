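"""Hierarchical fits: recovery, WAIC, p-direction, groups, trimming."""

import math

import numpy as np
import pandas as pd
import pytest

from vfprog import (
    ConvergenceError,
    DataError,
    GeneratorConfig,
    MCMCConfig,
    compare_waic,
    compute_waic,
    fit_exgauss_lmm,
    fit_grouped,
    generate_cohort,
    p_direction,
    summarize_cohort,
    trimming_analysis,
)
from vfprog.lmm import trim_series

QUICK = MCMCConfig(warmup=600, draws=400, thin=4, seed=5, min_ess=100)


def _flat_cohort(n, m, slopes, intercepts, sigma, seed, span_years=10.0):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, span_years, m)
    y = intercepts[:, None] + slopes[:, None] * t[None, :] + rng.normal(0, sigma, (n, m))
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"e{i:04d}" for i in range(n)], m),
            "time_years": np.tile(t, n),
            "md_db": y.ravel(),
        }
    )


# ------------------------------------------------------------- p-direction

def test_p_direction_closed_form_cases():
    rng = np.random.default_rng(0)
    all_pos = np.abs(rng.normal(size=2000)) + 0.01
    assert p_direction(all_pos) == pytest.approx(2 / 2000)
    sym = rng.normal(size=10**5)
    assert p_direction(sym) > 0.95
    shifted = rng.normal(1.0, 1.0, size=10**5)
    assert p_direction(shifted) == pytest.approx(2 * math.erfc(1 / math.sqrt(2)) / 2, abs=0.01)


def test_p_direction_contracts():
    with pytest.raises(DataError):
        p_direction(np.ones(100))
    with pytest.raises(DataError):
        p_direction(np.zeros(2000))


# --------------------------------------------------------------------- WAIC

def test_waic_hand_computed_oracle():
    # 2 observations x 3 draws, small enough to do by hand
    ll = np.array([[-1.0, -1.2, -0.8], [-2.0, -2.5, -1.5]])
    lppd, p = [], []
    for row in ll:
        lppd.append(math.log(sum(math.exp(v) for v in row) / 3))
        mean = sum(row) / 3
        p.append(sum((v - mean) ** 2 for v in row) / 2)  # ddof=1 as in loo
    expected = -2 * (sum(lppd) - sum(p))
    res = compute_waic(ll)
    assert res.waic == pytest.approx(expected, rel=1e-12)
    assert res.p_waic == pytest.approx(sum(p), rel=1e-12)
    pw = [-2 * (l - q) for l, q in zip(lppd, p)]
    mean_pw = sum(pw) / 2
    var_pw = sum((v - mean_pw) ** 2 for v in pw)  # ddof=1, n=2
    assert res.se == pytest.approx(math.sqrt(2 * var_pw), rel=1e-12)


def test_waic_against_arviz():
    import warnings

    import arviz as az

    rng = np.random.default_rng(1)
    ll = rng.normal(-2.0, 0.4, size=(2, 300, 40))
    mine = compute_waic(ll.reshape(-1, 40).T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = az.waic(az.from_dict(log_likelihood={"y": ll}), scale="deviance")
    s = 600
    # arviz uses the population variance for p_waic where loo (and we) use
    # the sample variance; the two are related by (s-1)/s exactly
    assert mine.p_waic * (s - 1) / s == pytest.approx(float(ref.p_waic), rel=1e-9)
    waic_az_adjusted = float(ref.elpd_waic) + 2 * (mine.p_waic - float(ref.p_waic))
    assert mine.waic == pytest.approx(waic_az_adjusted, rel=1e-9)
    assert mine.se == pytest.approx(float(ref.se), rel=0.02)


def test_waic_comparison_identical_models_and_contracts():
    rng = np.random.default_rng(2)
    ll = rng.normal(-1, 0.2, size=(30, 50))
    cmp_same = compare_waic(ll, ll)
    assert cmp_same.difference == 0.0
    assert cmp_same.se_difference == 0.0
    with pytest.raises(DataError):
        compute_waic(np.array([[np.inf, 0.0], [0.0, 0.0]]))
    with pytest.raises(DataError):
        compute_waic(np.ones((1, 5)))


# ------------------------------------------------------------ fitting: core

def test_data_contracts():
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=10, seed=0))
    with pytest.raises(DataError):  # too few eyes
        fit_exgauss_lmm(cohort, mcmc=QUICK)
    cohort2, _ = generate_cohort(GeneratorConfig(n_eyes=40, seed=0))
    short = cohort2.groupby("subject_id").head(2)
    with pytest.raises(DataError):  # eyes with < 3 tests
        fit_exgauss_lmm(short, mcmc=QUICK)


def test_nonconvergence_raises_with_diagnostics():
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=60, seed=3))
    with pytest.raises(ConvergenceError) as err:
        # 30 kept draws per chain can never reach the 400-ESS floor
        fit_exgauss_lmm(cohort, mcmc=MCMCConfig(warmup=50, draws=30, thin=1, seed=1))
    assert set(err.value.rhat) == {
        "lam_slope", "mu_slope", "lam_intercept", "mu_intercept", "sigma_e",
    }


def test_same_seed_reproduces_posterior():
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=60, seed=6))
    cfg = MCMCConfig(warmup=200, draws=100, thin=2, seed=42, strict=False)
    f1 = fit_exgauss_lmm(cohort, mcmc=cfg)
    f2 = fit_exgauss_lmm(cohort, mcmc=cfg)
    for k in f1.draws:
        np.testing.assert_array_equal(f1.draws[k], f2.draws[k])


def test_models_estimate_same_number_of_population_parameters(medium_fits):
    _, exg, gau = medium_fits
    assert len(exg.population_params) == len(gau.population_params) == 5


def test_recovery_on_synthetic_cohort(medium_fits):
    """The exGaussian fit separates the exponential mean from the learning
    offset; the Gaussian fit reports their (biased) sum."""
    truth, exg, gau = medium_fits
    true_mean = truth["true_slope"].mean()
    assert exg.mean("exp_mean_slope") == pytest.approx(true_mean, abs=0.05)
    lo, hi = exg.ci("exp_mean_slope")
    assert lo - 0.02 <= true_mean <= hi + 0.02
    assert exg.mean("mu_slope") == pytest.approx(0.094, abs=0.05)
    assert exg.mean("sigma_e") == pytest.approx(1.97, abs=0.08)
    # the Gaussian-LMM mean tracks the observed (learning-biased) mean
    assert gau.mean("mu_slope") == pytest.approx(true_mean + 0.094, abs=0.04)
    assert gau.mean("mu_slope") == pytest.approx(exg.mean("sample_mean_slope"), abs=0.04)


def test_gaussian_variance_is_mean_squared_slope_se(medium_fits):
    """The reported Gaussian variance equals the posterior mean of the
    average squared expected slope SE, recomputed from the raw data."""
    _, exg, _ = medium_fits
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=500, seed=7101))
    s = summarize_cohort(cohort)
    mean_inv_stt = float(np.mean(1.0 / s["s_tt"]))
    sig2_draws = exg.stacked("sigma_e") ** 2
    np.testing.assert_allclose(
        exg.stacked("gauss_var_slope"), sig2_draws * mean_inv_stt, rtol=1e-12
    )


def test_waic_prefers_exgauss_on_exgauss_data(medium_fits):
    _, exg, gau = medium_fits
    cmp = compare_waic(exg.pointwise_loglik(), gau.pointwise_loglik())
    assert cmp.difference < 0
    assert abs(cmp.difference) > 2 * cmp.se_difference


def test_fast_progressor_shrinkage(medium_fits):
    """Skewed random effects shrink fast progressors less: the exGaussian
    posterior slopes of truly fast eyes are at least as accurate as the
    Gaussian ones."""
    truth, exg, gau = medium_fits
    t = truth.set_index("subject_id")
    fast = t.index[t["true_slope"] < -1.0]
    assert len(fast) > 10
    re_e = exg.random_effects.set_index("subject_id").loc[fast, "slope_mean"]
    re_g = gau.random_effects.set_index("subject_id").loc[fast, "slope_mean"]
    err_e = np.abs(re_e - t.loc[fast, "true_slope"]).mean()
    err_g = np.abs(re_g - t.loc[fast, "true_slope"]).mean()
    assert err_e <= err_g + 1e-6


def test_null_cohort_concentrates_near_zero():
    """All true slopes zero: the exponential mean collapses toward 0 and the
    observed mean is approximately zero."""
    n, m = 300, 12
    cohort = _flat_cohort(
        n, m, np.zeros(n), np.full(n, -5.0), sigma=1.5, seed=9
    )
    fit = fit_exgauss_lmm(cohort, mcmc=MCMCConfig(
        warmup=600, draws=400, thin=4, seed=10, strict=False))
    assert -0.08 < fit.mean("exp_mean_slope") <= 0.0
    assert fit.mean("sample_mean_slope") == pytest.approx(0.0, abs=0.04)


def test_low_noise_identifiability():
    rng = np.random.default_rng(13)
    n, m = 200, 12
    slopes = -rng.exponential(0.4, n)
    cohort = _flat_cohort(n, m, slopes, np.full(n, -4.0), sigma=0.05, seed=14)
    fit = fit_exgauss_lmm(cohort, mcmc=MCMCConfig(
        warmup=600, draws=400, thin=4, seed=15, strict=False))
    assert fit.mean("exp_mean_slope") == pytest.approx(slopes.mean(), abs=0.02)
    assert fit.mean("mu_slope") == pytest.approx(0.0, abs=0.02)


# ------------------------------------------------------------------- groups

def test_grouped_fit_orders_severity_effects():
    frames, labels = [], {}
    for gi, (mean_rop, label) in enumerate(
        [(0.2, "early"), (0.4, "moderate"), (0.6, "advanced")]
    ):
        c, _ = generate_cohort(GeneratorConfig(
            n_eyes=250, lam_true=1 / mean_rop, seed=30 + gi))
        c = c.copy()
        c["subject_id"] = label[0] + c["subject_id"]
        frames.append(c)
        labels.update({sid: label for sid in c["subject_id"].unique()})
    cohort = pd.concat(frames, ignore_index=True)
    res = fit_grouped(cohort, labels, mcmc=MCMCConfig(
        warmup=600, draws=500, thin=4, seed=31, strict=False))
    means = {k: v.mean("exp_mean_slope") for k, v in res.groups.items()}
    assert means["early"] > means["moderate"] > means["advanced"]
    pw = res.pairwise.set_index(["parameter", "group_a", "group_b"])
    assert pw.loc[("exp_mean_slope", "advanced", "early"), "p_direction"] < 0.05
    assert pw.loc[("exp_mean_slope", "advanced", "moderate"), "p_direction"] < 0.05


def test_grouped_fit_contracts():
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=50, seed=33))
    ids = sorted(cohort["subject_id"].unique())
    labels = {sid: ("a" if i < 45 else "b") for i, sid in enumerate(ids)}
    with pytest.raises(DataError):  # group b has < 20 eyes
        fit_grouped(cohort, labels, mcmc=QUICK)
    with pytest.raises(DataError):  # unlabeled subject
        fit_grouped(cohort, {ids[0]: "a"}, mcmc=QUICK)


# ----------------------------------------------------------------- trimming

def test_trim_series_re_anchors_time():
    cohort, _ = generate_cohort(GeneratorConfig(n_eyes=40, seed=40))
    trimmed = trim_series(cohort, 2, min_series=8)
    per_eye = trimmed.groupby("subject_id")
    assert per_eye["time_years"].first().eq(0.0).all()
    assert per_eye.size().min() >= 8
    with pytest.raises(DataError):
        trim_series(cohort, 1, min_series=999)


def test_trimming_reduces_learning_offset():
    cohort, truth = generate_cohort(GeneratorConfig(n_eyes=400, seed=41))
    mcmc = MCMCConfig(warmup=600, draws=400, thin=4, seed=42, strict=False)
    table = trimming_analysis(cohort, max_trim=2, min_series=10, mcmc=mcmc)
    assert list(table["trim"]) == [0, 1, 2]
    # learning lives in the earliest tests: the Gaussian mean falls as they
    # are removed, the exponential mean stays put
    assert table["gauss_mean"].iloc[2] < table["gauss_mean"].iloc[0]
    true_mean = truth["true_slope"].mean()
    assert np.all(np.abs(table["exp_mean"] - true_mean) < 0.08)
    # k = 0 is exactly the plain fit with the same sampler seed
    plain = fit_exgauss_lmm(cohort, mcmc=mcmc)
    assert table["exp_mean"].iloc[0] == pytest.approx(
        plain.mean("exp_mean_slope"), abs=1e-12
    )
    with pytest.raises(DataError):
        trimming_analysis(cohort, max_trim=0, mcmc=mcmc)
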