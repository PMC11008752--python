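"""Two-arm neuroprotection-trial power: simulation engine and analytic form.

A trial draws "true" rates of progression from the denoised exponential
distribution — rate ``lam`` in the placebo arm and ``lam / (1 - E)`` in the
treatment arm, so a neuroprotective effect E is a proportional slowing of
every patient's true rate — attaches real(istic) baseline MDs as
intercepts, and adds Gaussian MD noise at the scheduled test times. The
treatment effect is then tested with:

* **Method 1** — the p value of the treatment-by-time interaction in a
  linear mixed model with correlated random intercepts and slopes.  For
  the balanced complete shared-schedule designs simulated here the REML
  solution is available in closed form (the profiled fixed effects are the
  per-arm means of the per-subject OLS coefficients and the interaction SE
  follows from the pooled between-subject coefficient covariance), with a
  numeric constrained REML fallback when the random-effect covariance
  estimate hits the positive-semidefinite boundary; the reference
  distribution is t with 2N - 2 degrees of freedom, the value the
  Satterthwaite approximation takes for this design.

* **Method 2** — Welch's unequal-variance t-test on the per-subject OLS
  slopes.

* **Analytic** — closed-form power of the Welch test computed from the
  exGaussian moments of the observed slopes: each arm's observed-slope
  variance is its exponential variance plus the schedule noise variance
  ``sigma_e^2 / S_tt``, and the mean difference is ``E / lam``; power comes
  from the noncentral t with Welch-Satterthwaite degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DataError, ParameterError

__all__ = [
    "TrialConfig",
    "ukgts_schedule",
    "simulate_trial",
    "method1_lmm_pvalue",
    "method2_ttest_pvalue",
    "analytic_power",
    "run_power_grid",
    "plot_power_curves",
]


def ukgts_schedule(n_visits: int = 8, years: float = 2.0, tests_per_visit: int = 2) -> np.ndarray:
    """Trial schedule of ``n_visits`` evenly spaced visits with same-day
    retests: 16 tests over 2 years by default."""
    visits = np.linspace(0.0, years, n_visits)
    return np.repeat(visits, tests_per_visit)


@dataclass(frozen=True)
class TrialConfig:
    """One cell of a trial-simulation design."""

    n_per_arm: int
    effect: float                        # E in [0, 1): proportional slowing
    lam: float = 1.0 / 0.38              # control-arm exponential rate
    schedule: tuple = tuple(ukgts_schedule())
    sigma_e: float | None = 1.97         # dB; None = per-subject from reference
    slope_offset: float = 0.0            # common offset (learning) in both arms
    n_sims: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ParameterError("n_per_arm must be >= 2")
        if not 0.0 <= self.effect < 1.0:
            raise ParameterError(f"effect must be in [0, 1), got {self.effect}")
        if self.lam <= 0:
            raise ParameterError("lam must be strictly positive")
        t = np.asarray(self.schedule, dtype=float)
        if t.size < 3 or np.ptp(t) == 0:
            raise DataError("schedule must have >= 3 tests at >= 2 distinct times")
        if self.sigma_e is not None and self.sigma_e < 0:
            raise ParameterError("sigma_e must be non-negative")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")


def _arm_rates(lam: float, effect: float) -> tuple[float, float]:
    # a 30% effect divides the rate by 0.7: treated mean is -(1-E)/lam
    return lam, lam / (1.0 - effect)


def simulate_trial(config: TrialConfig, reference: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Simulate one two-arm trial as a long-format table.

    ``reference`` is a per-subject summary table (columns ``intercept`` and
    ``resid_se``, e.g. from :func:`vfprog.regression.summarize_cohort`); 2N
    subjects are sampled without replacement, their baseline MD becomes the
    simulated intercept and (when ``config.sigma_e`` is None) their residual
    SE the subject-specific noise SD.
    """
    for col in ("intercept", "resid_se"):
        if col not in reference.columns:
            raise DataError(f"reference table is missing column {col!r}")
    n = config.n_per_arm
    if len(reference) < 2 * n:
        raise DataError(
            f"reference has {len(reference)} subjects; need >= {2 * n} "
            "for sampling without replacement"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.asarray(config.schedule, dtype=float)
    pick = rng.choice(len(reference), size=2 * n, replace=False)
    base = reference.iloc[pick].reset_index(drop=True)
    rate_c, rate_t = _arm_rates(config.lam, config.effect)
    rates = np.r_[np.full(n, rate_c), np.full(n, rate_t)]
    slopes = -rng.exponential(1.0 / rates) + config.slope_offset
    sig = (
        base["resid_se"].to_numpy()
        if config.sigma_e is None
        else np.full(2 * n, config.sigma_e)
    )
    y = (
        base["intercept"].to_numpy()[:, None]
        + slopes[:, None] * t[None, :]
        + rng.normal(0.0, sig[:, None], size=(2 * n, t.size))
    )
    width = len(str(2 * n))
    return pd.DataFrame(
        {
            "subject_id": np.repeat([f"s{i + 1:0{width}d}" for i in range(2 * n)], t.size),
            "arm": np.repeat(np.r_[["control"] * n, ["treated"] * n], t.size),
            "time_years": np.tile(t, 2 * n),
            "md_db": y.ravel(),
        }
    )


# --------------------------------------------------------------------------
# per-trial test methods

def _trial_arrays(trial: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pivot a balanced shared-schedule trial to (t, Y_control, Y_treated)."""
    for col in ("subject_id", "arm", "time_years", "md_db"):
        if col not in trial.columns:
            raise DataError(f"trial table is missing column {col!r}")
    arms = set(trial["arm"].unique())
    if arms != {"control", "treated"}:
        raise DataError(f"expected arms control/treated, got {sorted(arms)}")
    df = trial.sort_values(["arm", "subject_id", "time_years"], kind="stable")
    counts = df.groupby("subject_id").size()
    m = counts.iloc[0]
    if not (counts == m).all():
        raise DataError("unbalanced trial: subjects differ in test counts")
    t = df["time_years"].to_numpy()[:m]
    times = df["md_db"].to_numpy().reshape(-1, m)
    tmat = df["time_years"].to_numpy().reshape(-1, m)
    if not np.allclose(tmat, t[None, :]):
        raise DataError("subjects do not share a common schedule")
    n_c = df[df["arm"] == "control"]["subject_id"].nunique()
    return t, times[:n_c], times[n_c:]


def _ols_coefs(t: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row OLS (intercept, slope) of Y on t, plus residual sums of squares."""
    W = np.c_[np.ones_like(t), t]
    P = W @ np.linalg.inv(W.T @ W)          # m x 2
    C = Y @ P                                # rows x 2
    resid = Y - C @ W.T
    return C, np.einsum("...i,...i->...", resid, resid)


def method2_ttest_pvalue(trial: pd.DataFrame) -> float:
    """Welch two-sample t-test on per-subject OLS slopes (two-sided)."""
    t, Yc, Yt = _trial_arrays(trial)
    bc = _ols_coefs(t, Yc)[0][:, 1]
    bt = _ols_coefs(t, Yt)[0][:, 1]
    if np.var(bc) == 0 and np.var(bt) == 0:
        if np.allclose(bc.mean(), bt.mean()):
            return 1.0
        raise DataError("degenerate slopes: zero variance in both arms")
    return float(stats.ttest_ind(bt, bc, equal_var=False).pvalue)


def _reml_numeric(t, Yc, Yt):
    """Constrained REML for the bivariate random-coefficient model; returns
    (interaction estimate, SE). Used when the closed form hits the PSD
    boundary."""
    m = t.size
    W = np.c_[np.ones_like(t), t]
    Y = np.vstack([Yc, Yt])
    n_c, n_t = len(Yc), len(Yt)
    arm = np.r_[np.zeros(n_c), np.ones(n_t)]
    # fixed design per subject: [1, t, arm, arm*t]
    Xs = np.stack([np.c_[W, a * W] for a in arm])  # (n, m, 4)

    def neg2reml(theta):
        sig2 = np.exp(theta[0])
        l11, l21, l22 = np.exp(theta[1]), theta[2], np.exp(theta[3])
        L = np.array([[l11, 0.0], [l21, l22]])
        V = sig2 * np.eye(m) + W @ (L @ L.T) @ W.T
        try:
            Vi = np.linalg.inv(V)
            _, logdetV = np.linalg.slogdet(V)
        except np.linalg.LinAlgError:
            return np.inf
        XtVi = np.einsum("nmi,mk->nik", Xs, Vi)
        A = np.einsum("nik,nkj->ij", XtVi, Xs)
        hvec = np.einsum("nik,nk->i", XtVi, Y)
        beta = np.linalg.solve(A, hvec)
        r = Y - np.einsum("nmi,i->nm", Xs, beta)
        quad = np.einsum("nm,mk,nk->", r, Vi, r)
        _, logdetA = np.linalg.slogdet(A)
        return (n_c + n_t) * logdetV + quad + logdetA

    # start from the moment estimate projected onto the PSD cone
    C, rss = _ols_coefs(t, Y)
    sig0 = np.sqrt(rss.sum() / ((n_c + n_t) * (m - 2)))
    d = C - np.where(arm[:, None] > 0, C[n_c:].mean(axis=0), C[:n_c].mean(axis=0))
    S = d.T @ d / (n_c + n_t - 2)
    G0 = S - sig0**2 * np.linalg.inv(W.T @ W)
    evals, evecs = np.linalg.eigh(G0)
    G0 = (evecs * np.maximum(evals, 1e-4)) @ evecs.T
    L0 = np.linalg.cholesky(G0)
    res = optimize.minimize(
        neg2reml,
        np.array([2 * np.log(sig0), np.log(L0[0, 0]), L0[1, 0], np.log(L0[1, 1])]),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    theta = res.x
    sig2 = np.exp(theta[0])
    L = np.array([[np.exp(theta[1]), 0.0], [theta[2], np.exp(theta[3])]])
    V = sig2 * np.eye(m) + W @ (L @ L.T) @ W.T
    Vi = np.linalg.inv(V)
    XtVi = np.einsum("nmi,mk->nik", Xs, Vi)
    A = np.einsum("nik,nkj->ij", XtVi, Xs)
    hvec = np.einsum("nik,nk->i", XtVi, Y)
    beta = np.linalg.solve(A, hvec)
    cov = np.linalg.inv(A)
    return float(beta[3]), float(np.sqrt(cov[3, 3]))


def method1_lmm_pvalue(trial: pd.DataFrame, backend: str = "fast") -> float:
    """Two-sided p value for the treatment-by-time interaction in a mixed
    model with correlated random intercepts and slopes.

    ``backend="fast"`` uses the exact REML solution for balanced complete
    shared-schedule data (t reference, 2N - 2 df); ``backend="statsmodels"``
    fits ``statsmodels`` MixedLM (Wald z reference).
    """
    if backend == "statsmodels":
        return _method1_statsmodels(trial)
    if backend != "fast":
        raise ParameterError(f"unknown backend {backend!r}")
    t, Yc, Yt = _trial_arrays(trial)
    est, se, _ = _fast_lmm_stats(t, Yc[None], Yt[None])
    df = len(Yc) + len(Yt) - 2
    return float(2.0 * stats.t.sf(abs(est[0] / se[0]), df))


def _method1_statsmodels(trial: pd.DataFrame) -> float:
    import statsmodels.formula.api as smf

    df = trial.copy()
    df["treated"] = (df["arm"] == "treated").astype(float)
    model = smf.mixedlm(
        "md_db ~ time_years * treated",
        df,
        groups=df["subject_id"],
        re_formula="~time_years",
    )
    fit = model.fit(reml=True)
    return float(fit.pvalues["time_years:treated"])


def _fast_lmm_stats(t, Yc, Yt):
    """Vectorized closed-form REML interaction estimate/SE for stacked sims.

    ``Yc``/``Yt`` have shape (n_sims, N, m). For balanced shared-schedule
    data the GLS fixed effects equal the per-arm means of the per-subject
    OLS coefficients for any random-effect covariance, and the REML
    variance of the interaction is the pooled between-subject slope
    variance times 2/N — provided the implied random-effect covariance
    G = S_c - sigma^2 (W'W)^-1 stays positive semidefinite. Boundary sims
    are re-fit by numeric constrained REML.
    """
    n_sims, n_c, m = Yc.shape
    n_t = Yt.shape[1]
    W = np.c_[np.ones_like(t), t]
    WtWi = np.linalg.inv(W.T @ W)
    Cc, rss_c = _ols_coefs(t, Yc)
    Ct, rss_t = _ols_coefs(t, Yt)
    sig2 = (rss_c.sum(axis=1) + rss_t.sum(axis=1)) / ((n_c + n_t) * (m - 2))
    dc = Cc - Cc.mean(axis=1, keepdims=True)
    dt = Ct - Ct.mean(axis=1, keepdims=True)
    S = (
        np.einsum("sni,snj->sij", dc, dc) + np.einsum("sni,snj->sij", dt, dt)
    ) / (n_c + n_t - 2)
    est = Ct[:, :, 1].mean(axis=1) - Cc[:, :, 1].mean(axis=1)
    se = np.sqrt(S[:, 1, 1] * (1.0 / n_c + 1.0 / n_t))
    G = S - sig2[:, None, None] * WtWi[None]
    on_boundary = ~(
        (G[:, 0, 0] >= 0)
        & (G[:, 1, 1] >= 0)
        & (G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] ** 2 >= 0)
    )
    for s in np.nonzero(on_boundary)[0]:
        est_s, se_s = _reml_numeric(t, Yc[s], Yt[s])
        est[s] = est_s
        se[s] = se_s
    return est, se, int(on_boundary.sum())


# --------------------------------------------------------------------------
# analytic power

def analytic_power(
    lam: float,
    effect: float,
    sigma_e: float,
    schedule,
    n_per_arm: int,
    alpha: float = 0.05,
) -> float:
    """Closed-form power of the Welch slope t-test for a two-arm trial.

    Observed-slope moments per arm: control mean -1/lam and variance
    1/lam^2 + v; treated mean -(1-E)/lam and variance (1-E)^2/lam^2 + v,
    where v = sigma_e^2 / S_tt is the schedule noise variance. A learning
    offset common to both arms shifts both means equally and cancels from
    the difference, so it does not appear here.
    """
    if not 0.0 <= effect < 1.0:
        raise ParameterError(f"effect must be in [0, 1), got {effect}")
    if lam <= 0 or sigma_e < 0:
        raise ParameterError("lam must be positive and sigma_e non-negative")
    t = np.asarray(schedule, dtype=float)
    if t.size < 3 or np.ptp(t) == 0:
        raise DataError("schedule must have >= 3 tests at >= 2 distinct times")
    if n_per_arm < 2:
        raise ParameterError("n_per_arm must be >= 2")
    tc = t - t.mean()
    v = sigma_e**2 / float(tc @ tc)
    var_c = 1.0 / lam**2 + v
    var_t = (1.0 - effect) ** 2 / lam**2 + v
    n = n_per_arm
    se = np.sqrt((var_c + var_t) / n)
    ncp = (effect / lam) / se
    df = (var_c / n + var_t / n) ** 2 / (
        (var_c / n) ** 2 / (n - 1) + (var_t / n) ** 2 / (n - 1)
    )
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


# --------------------------------------------------------------------------
# vectorized grid engine

def _simulate_cell(rng, n_sims, n_per_arm, lam, effect, sigma_e, schedule,
                   reference=None, slope_offset=0.0, chunk=200):
    """Simulate ``n_sims`` paired trials of one design cell; returns stacked
    (Yc, Yt) arrays, generating full MD series in memory-bounded chunks."""
    t = np.asarray(schedule, dtype=float)
    m = t.size
    n = n_per_arm
    rate_c, rate_t = _arm_rates(lam, effect)
    Yc = np.empty((n_sims, n, m))
    Yt = np.empty((n_sims, n, m))
    if reference is not None and len(reference) < 2 * n:
        raise DataError("reference too small for sampling without replacement")
    for lo in range(0, n_sims, chunk):
        hi = min(lo + chunk, n_sims)
        k = hi - lo
        slopes_c = -rng.exponential(1.0 / rate_c, size=(k, n)) + slope_offset
        slopes_t = -rng.exponential(1.0 / rate_t, size=(k, n)) + slope_offset
        if reference is None:
            icept = np.zeros((k, 2 * n))
            sig = np.full((k, 2 * n), sigma_e if sigma_e is not None else 0.0)
        else:
            ic = reference["intercept"].to_numpy()
            rs = reference["resid_se"].to_numpy()
            picks = np.stack(
                [rng.choice(len(reference), size=2 * n, replace=False) for _ in range(k)]
            )
            icept = ic[picks]
            sig = rs[picks] if sigma_e is None else np.full((k, 2 * n), sigma_e)
        noise = rng.standard_normal((k, 2 * n, m)) * sig[:, :, None]
        Yc[lo:hi] = icept[:, :n, None] + slopes_c[:, :, None] * t[None, None, :] + noise[:, :n]
        Yt[lo:hi] = icept[:, n:, None] + slopes_t[:, :, None] * t[None, None, :] + noise[:, n:]
    return t, Yc, Yt


def _welch_pvalues(t, Yc, Yt):
    bc = _ols_coefs(t, Yc)[0][:, :, 1]
    bt = _ols_coefs(t, Yt)[0][:, :, 1]
    n_c, n_t = bc.shape[1], bt.shape[1]
    vc = bc.var(axis=1, ddof=1) / n_c
    vt = bt.var(axis=1, ddof=1) / n_t
    tstat = (bt.mean(axis=1) - bc.mean(axis=1)) / np.sqrt(vc + vt)
    df = (vc + vt) ** 2 / (vc**2 / (n_c - 1) + vt**2 / (n_t - 1))
    return 2.0 * stats.t.sf(np.abs(tstat), df)


def run_power_grid(
    n_per_arm_list,
    effect_list,
    lam: float = 1.0 / 0.38,
    sigma_e: float | None = 1.97,
    schedule=None,
    n_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    reference: pd.DataFrame | None = None,
    methods: tuple = ("ttest",),
    slope_offset: float = 0.0,
) -> pd.DataFrame:
    """Monte-Carlo power over an (N, E) grid, with analytic predictions.

    Each cell simulates ``n_sims`` paired trials (per-cell seeds derived
    from ``seed``) and reports the proportion of p < alpha per method, the
    binomial Monte-Carlo SE, a 1.96-SE confidence interval, the analytic
    prediction, and — when both methods run — the number of simulations on
    which they disagree about significance.
    """
    schedule = ukgts_schedule() if schedule is None else np.asarray(schedule, float)
    for meth in methods:
        if meth not in ("ttest", "lmm"):
            raise ParameterError(f"unknown method {meth!r}")
    cells = [(int(n), float(e)) for e in effect_list for n in n_per_arm_list]
    seeds = np.random.SeedSequence(seed).spawn(len(cells))
    sig_for_analytic = (
        sigma_e
        if sigma_e is not None
        else float(np.sqrt(np.mean(reference["resid_se"].to_numpy() ** 2)))
    )
    rows = []
    for (n, e), seq in zip(cells, seeds):
        rng = np.random.default_rng(seq)
        t, Yc, Yt = _simulate_cell(
            rng, n_sims, n, lam, e, sigma_e, schedule,
            reference=reference, slope_offset=slope_offset,
        )
        row = {"n_per_arm": n, "effect": e, "n_sims": n_sims}
        p_by_method = {}
        if "ttest" in methods:
            p_by_method["ttest"] = _welch_pvalues(t, Yc, Yt)
        if "lmm" in methods:
            est, se, n_boundary = _fast_lmm_stats(t, Yc, Yt)
            df = 2 * n - 2
            p_by_method["lmm"] = 2.0 * stats.t.sf(np.abs(est / se), df)
            row["n_boundary"] = n_boundary
        for meth, p in p_by_method.items():
            power = float(np.mean(p < alpha))
            row[f"power_{meth}"] = power
            row[f"mc_se_{meth}"] = float(np.sqrt(power * (1 - power) / n_sims))
        first = methods[0]
        row["ci_lo"] = max(row[f"power_{first}"] - 1.96 * row[f"mc_se_{first}"], 0.0)
        row["ci_hi"] = min(row[f"power_{first}"] + 1.96 * row[f"mc_se_{first}"], 1.0)
        if len(p_by_method) == 2:
            row["disagreements"] = int(
                np.sum((p_by_method["ttest"] < alpha) != (p_by_method["lmm"] < alpha))
            )
        row["power_analytic"] = analytic_power(
            lam, e, sig_for_analytic, schedule, n, alpha
        )
        rows.append(row)
    return pd.DataFrame(rows)


def plot_power_curves(grid: pd.DataFrame, method: str = "ttest"):
    """Power curves per effect size with 1.96-SE error bars and the analytic
    prediction overlaid; returns a matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for e, sub in grid.groupby("effect"):
        sub = sub.sort_values("n_per_arm")
        ax.errorbar(
            sub["n_per_arm"], sub[f"power_{method}"],
            yerr=1.96 * sub[f"mc_se_{method}"],
            fmt="o", capsize=3, label=f"simulated, E = {e:.0%}",
        )
        ax.plot(sub["n_per_arm"], sub["power_analytic"], "-", alpha=0.7)
    ax.axhline(0.05, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("sample size per arm")
    ax.set_ylabel("power")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
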