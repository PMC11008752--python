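"""Bayesian hierarchical linear mixed models for MD progression rates.

Two models of a long-format cohort ``y_ij ~ Normal(a_i + b_i * t_ij, sigma_e^2)``:

* **exGaussian-LMM** — the random slope of eye *i* is a population offset
  minus a latent exponential "true" progression component,

      b_i = mu_b - Xb_i,   Xb_i ~ Exp(lam_b),

  and likewise for the intercept. The Gaussian component of the exGaussian
  distribution of *observed* (OLS-estimated) slopes is not an extra free
  random effect: it is the slope estimation noise itself, whose per-eye SD
  ``sigma_e / sqrt(S_tt,i)`` is a deterministic function of the residual SD
  and the schedule. ``mu_b`` is therefore the mean of that Gaussian
  component (learning offset) and the implied between-subject variance of
  observed slopes is ``1/lam_b^2 + mean(sigma_e^2 / S_tt)`` — no separate
  random-effect variance is estimated, so the model has the same number of
  population parameters (five) as the Gaussian-LMM below.

* **Gaussian-LMM** — the standard reference model, with independent
  Gaussian random intercepts and slopes of estimated means and SDs.

Inference is by a blocked Gibbs sampler: conjugate bivariate-normal updates
for the per-eye effects, truncated-normal draws for the latent exponential
components, conjugate Gamma/normal updates for the population rate and mean
parameters, adaptive random-walk Metropolis for the scale parameters, and a
translation move along the (mu, latent-X) ridge that removes the slow
mixing direction of the sum decomposition. Split-R-hat and bulk ESS are
computed with arviz; pointwise log-likelihoods are retained for WAIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import ConvergenceError, DataError, ParameterError

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "PosteriorSummary",
    "WaicResult",
    "WaicComparison",
    "fit_exgauss_lmm",
    "fit_gaussian_lmm",
    "compute_waic",
    "compare_waic",
    "fit_grouped",
    "GroupedResult",
    "p_direction",
    "trimming_analysis",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PriorConfig:
    """Prior hyperparameters for the population parameters.

    ``default-weak`` is mildly regularizing; ``practically-uninformative``
    widens every scale tenfold and is the variant used for WAIC comparisons,
    so that the prior information matches what the Gaussian-LMM receives.
    """

    variant: str = "default-weak"
    lam_gamma_rate: float = 0.1        # lam ~ Gamma(shape=1, rate); vague scale
    mu_slope_sd: float = 1.0           # dB/year
    mu_intercept_sd: float = 2.0       # dB
    sigma_e_scale: float = 5.0         # dB, Half-Normal
    re_slope_sd_scale: float = 2.0     # dB/year, Half-Normal (Gaussian-LMM tau_b)
    re_intercept_sd_scale: float = 10.0  # dB, Half-Normal (Gaussian-LMM tau_a)

    def __post_init__(self):
        if self.variant not in ("default-weak", "practically-uninformative"):
            raise ParameterError(f"unknown prior variant {self.variant!r}")
        for name in (
            "lam_gamma_rate", "mu_slope_sd", "mu_intercept_sd",
            "sigma_e_scale", "re_slope_sd_scale", "re_intercept_sd_scale",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    @classmethod
    def practically_uninformative(cls) -> "PriorConfig":
        base = cls()
        return cls(
            variant="practically-uninformative",
            lam_gamma_rate=base.lam_gamma_rate / 10.0,
            mu_slope_sd=base.mu_slope_sd * 10.0,
            mu_intercept_sd=base.mu_intercept_sd * 10.0,
            sigma_e_scale=base.sigma_e_scale * 10.0,
            re_slope_sd_scale=base.re_slope_sd_scale * 10.0,
            re_intercept_sd_scale=base.re_intercept_sd_scale * 10.0,
        )


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings: chain count, warmup/kept draws, seed, diagnostics."""

    chains: int = 2
    warmup: int = 1500
    draws: int = 1000                  # kept draws per chain
    thin: int = 16                     # sweeps per kept draw
    seed: int = 0
    rhat_max: float = 1.01
    min_ess: float = 400.0
    strict: bool = True                # raise ConvergenceError on failed diagnostics
    save_loglik: bool = True
    save_random_effects: bool = True

    def __post_init__(self):
        if self.chains < 2:
            raise ParameterError("at least 2 chains are required")
        if self.warmup < 1 or self.draws < 1 or self.thin < 1:
            raise ParameterError("warmup, draws and thin must be >= 1")


# --------------------------------------------------------------------------
# results

@dataclass
class PosteriorSummary:
    """Posterior draws and summaries of a hierarchical fit."""

    model: str
    draws: dict                         # name -> array (chains, draws)
    population_params: tuple
    rhat: dict
    ess: dict
    n_eyes: int
    n_obs: int
    subject_ids: np.ndarray
    log_likelihood: np.ndarray | None = None   # (chains, draws, n_obs)
    random_effects: pd.DataFrame | None = None

    def stacked(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).reshape(-1)

    def mean(self, name: str) -> float:
        return float(self.stacked(name).mean())

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.stacked(name), [alpha, 1.0 - alpha])
        return float(lo), float(hi)

    def pointwise_loglik(self) -> np.ndarray:
        """Pointwise log-likelihood as an (n_obs, total_draws) matrix."""
        if self.log_likelihood is None:
            raise DataError("fit was run with save_loglik=False")
        ll = self.log_likelihood
        return np.ascontiguousarray(
            ll.reshape(-1, ll.shape[-1]).T.astype(np.float64)
        )

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.draws:
            lo, hi = self.ci(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": self.mean(name),
                    "ci2.5": lo,
                    "ci97.5": hi,
                    "rhat": self.rhat.get(name, np.nan),
                    "ess_bulk": self.ess.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        out = {"model": self.model, "n_eyes": self.n_eyes, "n_obs": self.n_obs}
        out["parameters"] = {
            r["parameter"]: {
                k: (None if pd.isna(r[k]) else float(r[k]))
                for k in ("mean", "ci2.5", "ci97.5", "rhat", "ess_bulk")
            }
            for r in self.summary().to_dict("records")
        }
        return out


@dataclass(frozen=True)
class WaicResult:
    """WAIC on the deviance scale (-2 * elpd; lower is better)."""

    waic: float
    se: float
    p_waic: float
    pointwise: np.ndarray  # per-observation -2*(lppd_i - p_i)


@dataclass(frozen=True)
class WaicComparison:
    result_a: WaicResult
    result_b: WaicResult
    difference: float       # waic_a - waic_b
    se_difference: float


# --------------------------------------------------------------------------
# data preparation

class _EyeData:
    """Per-eye sufficient statistics of a long-format cohort."""

    def __init__(self, cohort: pd.DataFrame, min_eyes: int = 30):
        for col in ("subject_id", "time_years", "md_db"):
            if col not in cohort.columns:
                raise DataError(f"cohort table is missing column {col!r}")
        df = cohort.sort_values(["subject_id", "time_years"], kind="stable")
        ids, idx = np.unique(df["subject_id"].to_numpy(), return_inverse=True)
        if ids.size < min_eyes:
            raise DataError(f"need at least {min_eyes} eyes, got {ids.size}")
        t = df["time_years"].to_numpy(dtype=float)
        y = df["md_db"].to_numpy(dtype=float)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise DataError("time_years and md_db must be finite")
        n = np.bincount(idx)
        if n.min() < 3:
            bad = ids[n < 3]
            raise DataError(f"every eye needs >= 3 tests; offending: {bad[:5].tolist()}")
        self.ids = ids
        self.idx = idx
        self.t = t
        self.y = y
        self.n = n.astype(float)
        self.St = np.bincount(idx, weights=t)
        self.Stt = np.bincount(idx, weights=t * t)
        self.Sy = np.bincount(idx, weights=y)
        self.Sty = np.bincount(idx, weights=t * y)
        self.Syy = np.bincount(idx, weights=y * y)
        self.t_bar = self.St / self.n
        self.stt_c = self.Stt - self.n * self.t_bar**2
        if np.any(self.stt_c <= 1e-12):
            bad = ids[self.stt_c <= 1e-12]
            raise DataError(f"degenerate schedules (all times equal): {bad[:5].tolist()}")
        # expected-SE factors: slope SD = sigma_e*sb_factor, intercept likewise
        self.sb_factor = 1.0 / np.sqrt(self.stt_c)
        self.sa_factor = np.sqrt(1.0 / self.n + self.t_bar**2 / self.stt_c)
        self.n_eyes = ids.size
        self.n_obs = t.size


def _ols_start(data: _EyeData) -> tuple[np.ndarray, np.ndarray, float]:
    b = (data.Sty - data.n * data.t_bar * (data.Sy / data.n)) / data.stt_c
    a = data.Sy / data.n - b * data.t_bar
    rss = np.maximum(
        data.Syy - 2 * a * data.Sy - 2 * b * data.Sty
        + a**2 * data.n + 2 * a * b * data.St + b**2 * data.Stt,
        0.0,
    )
    sigma = float(np.sqrt(rss.sum() / np.maximum(data.n - 2, 1).sum()))
    return a, b, max(sigma, 0.05)


# --------------------------------------------------------------------------
# sampling primitives

def _truncnorm_pos(rng, mean, sd):
    """Vectorized draws from Normal(mean, sd) truncated to (0, inf)."""
    alpha = -np.asarray(mean) / sd
    u = rng.uniform(size=alpha.shape)
    z = np.empty_like(alpha)
    easy = alpha < 30.0
    tail = special.ndtr(-alpha[easy])
    z[easy] = -special.ndtri(u[easy] * tail)
    if np.any(~easy):
        # deep tail: Normal | Z > alpha ~ alpha + Exp(alpha) to high accuracy
        a = alpha[~easy]
        z[~easy] = a - np.log(u[~easy]) / a
    return mean + sd * z


class _AdaptiveStep:
    """Random-walk scale adapted toward a target acceptance rate in warmup."""

    def __init__(self, scale: float, target: float = 0.44, batch: int = 50):
        self.scale = scale
        self.target = target
        self.batch = batch
        self._acc = 0
        self._count = 0

    def update(self, accepted: bool, adapting: bool):
        if not adapting:
            return
        self._acc += accepted
        self._count += 1
        if self._count == self.batch:
            rate = self._acc / self.batch
            self.scale *= np.exp(0.6 * (rate - self.target))
            self._acc = 0
            self._count = 0


def _bvn_effects_update(rng, data, sigma_e, prior_mean_a, prior_mean_b, sa, sb):
    """Conjugate joint draw of (a_i, b_i) given priors N(prior_mean, s^2)."""
    inv_s2 = 1.0 / sigma_e**2
    A11 = data.n * inv_s2 + 1.0 / sa**2
    A12 = data.St * inv_s2
    A22 = data.Stt * inv_s2 + 1.0 / sb**2
    h1 = data.Sy * inv_s2 + prior_mean_a / sa**2
    h2 = data.Sty * inv_s2 + prior_mean_b / sb**2
    det = A11 * A22 - A12**2
    c11 = A22 / det
    c12 = -A12 / det
    c22 = A11 / det
    m_a = c11 * h1 + c12 * h2
    m_b = c12 * h1 + c22 * h2
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21**2, 1e-300))
    z1 = rng.standard_normal(data.n_eyes)
    z2 = rng.standard_normal(data.n_eyes)
    a = m_a + l11 * z1
    b = m_b + l21 * z1 + l22 * z2
    return a, b


def _rss(data, a, b) -> float:
    return float(
        np.sum(
            data.Syy - 2 * a * data.Sy - 2 * b * data.Sty
            + a**2 * data.n + 2 * a * b * data.St + b**2 * data.Stt
        )
    )


def _pointwise_loglik(data, a, b, sigma_e) -> np.ndarray:
    resid = data.y - a[data.idx] - b[data.idx] * data.t
    return (-_LOG_SQRT_2PI - np.log(sigma_e) - 0.5 * (resid / sigma_e) ** 2).astype(
        np.float32
    )


# --------------------------------------------------------------------------
# exGaussian-LMM sampler

def _run_exgauss_chain(data, priors, mcmc, chain_seed, collect):
    rng = np.random.default_rng(chain_seed)
    a, b, sigma_e = _ols_start(data)
    sigma_e *= rng.uniform(0.9, 1.1)
    # method-of-moments start: exponential variance ~ excess of the observed
    # slope variance over the schedule-implied estimation variance
    est_var_b = sigma_e**2 * float(np.mean(data.sb_factor**2))
    inv_lam_b = float(np.sqrt(max(np.var(b) - est_var_b, 1e-4)))
    mu_b = float(b.mean()) + inv_lam_b + rng.normal(0.0, 0.02)
    est_var_a = sigma_e**2 * float(np.mean(data.sa_factor**2))
    inv_lam_a = float(np.sqrt(max(np.var(a) - est_var_a, 0.25)))
    mu_a = float(a.mean()) + inv_lam_a + rng.normal(0.0, 0.1)
    Xb = np.maximum(mu_b - b, 1e-3)
    Xa = np.maximum(mu_a - a, 1e-2)
    b = mu_b - Xb
    a = mu_a - Xa
    lam_b = 1.0 / max(float(Xb.mean()), 1e-3)
    lam_a = 1.0 / max(float(Xa.mean()), 1e-2)

    sigma_step = _AdaptiveStep(0.02, target=0.35)
    shift_b = _AdaptiveStep(0.02)
    shift_a = _AdaptiveStep(0.2)

    n_iter = mcmc.warmup + mcmc.draws * mcmc.thin
    out = {
        name: np.empty(mcmc.draws)
        for name in ("lam_slope", "mu_slope", "lam_intercept", "mu_intercept", "sigma_e")
    }
    ll_store = (
        np.empty((mcmc.draws, data.n_obs), dtype=np.float32) if collect else None
    )
    re_a = np.zeros(data.n_eyes)
    re_b = np.zeros(data.n_eyes)

    # population-level sufficient statistics for the (mu_a, mu_b) update
    T_sum = float(data.St.sum())
    TT_sum = float(data.Stt.sum())
    Sy_tot = float(data.Sy.sum())
    Sty_tot = float(data.Sty.sum())

    mean_sb_f2 = float(np.mean(data.sb_factor**2))
    for it in range(n_iter):
        adapting = it < mcmc.warmup
        inv_s2 = 1.0 / sigma_e**2

        # per-eye effects: b_i = mu_b - Xb_i, a_i = mu_a - Xa_i. Conditionally
        # each is a one-sided truncated normal (exponential tilt of the
        # Gaussian likelihood); alternate twice for the a-b correlation.
        v_b = sigma_e**2 / data.Stt
        v_a = sigma_e**2 / data.n
        for _ in range(2):
            b_star = (data.Sty - a * data.St) / data.Stt
            Xb = _truncnorm_pos(rng, mu_b - b_star - lam_b * v_b, np.sqrt(v_b))
            b = mu_b - Xb
            a_star = (data.Sy - b * data.St) / data.n
            Xa = _truncnorm_pos(rng, mu_a - a_star - lam_a * v_a, np.sqrt(v_a))
            a = mu_a - Xa

        lam_b = rng.gamma(1.0 + data.n_eyes, 1.0 / (priors.lam_gamma_rate + Xb.sum()))
        lam_a = rng.gamma(1.0 + data.n_eyes, 1.0 / (priors.lam_gamma_rate + Xa.sum()))

        # joint conjugate update of (mu_a, mu_b) given the latents:
        # y_ij + Xa_i + Xb_i t_ij = mu_a + mu_b t_ij + eps
        A11 = data.n_obs * inv_s2 + 1.0 / priors.mu_intercept_sd**2
        A12 = T_sum * inv_s2
        A22 = TT_sum * inv_s2 + 1.0 / priors.mu_slope_sd**2
        h1 = (Sy_tot + float(Xa @ data.n) + float(Xb @ data.St)) * inv_s2
        h2 = (Sty_tot + float(Xa @ data.St) + float(Xb @ data.Stt)) * inv_s2
        det = A11 * A22 - A12**2
        c11, c12, c22 = A22 / det, -A12 / det, A11 / det
        m_a = c11 * h1 + c12 * h2
        m_b = c12 * h1 + c22 * h2
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(max(c22 - l21**2, 1e-300))
        z1, z2 = rng.standard_normal(2)
        mu_a = m_a + l11 * z1
        mu_b = m_b + l21 * z1 + l22 * z2
        a = mu_a - Xa
        b = mu_b - Xb

        # ridge translation: shifting (mu, all latent X) together leaves
        # every a_i/b_i — hence the likelihood — invariant; this move mixes
        # the decomposition between the exponential and Gaussian components.
        # Repeated a few times per sweep — it is O(1) next to the vector
        # updates and dominates the mixing of mu and lam.
        for which in ("b", "a") * 6:
            step = shift_b if which == "b" else shift_a
            delta = rng.normal(0.0, step.scale)
            if which == "b":
                ok = delta > -Xb.min()
                logr = (
                    -lam_b * data.n_eyes * delta
                    - ((mu_b + delta) ** 2 - mu_b**2) / (2 * priors.mu_slope_sd**2)
                    if ok
                    else -np.inf
                )
                if np.log(rng.uniform()) < logr:
                    mu_b += delta
                    Xb = Xb + delta
                    step.update(True, adapting)
                else:
                    step.update(False, adapting)
            else:
                ok = delta > -Xa.min()
                logr = (
                    -lam_a * data.n_eyes * delta
                    - ((mu_a + delta) ** 2 - mu_a**2) / (2 * priors.mu_intercept_sd**2)
                    if ok
                    else -np.inf
                )
                if np.log(rng.uniform()) < logr:
                    mu_a += delta
                    Xa = Xa + delta
                    step.update(True, adapting)
                else:
                    step.update(False, adapting)

        # sigma_e: random-walk Metropolis on log sigma (Half-Normal prior)
        q = _rss(data, a, b)
        ntot = data.n_obs

        def logpost(s):
            return (
                -(ntot - 1) * np.log(s)
                - q / (2 * s**2)
                - s**2 / (2 * priors.sigma_e_scale**2)
            )

        for _ in range(3):
            prop = sigma_e * np.exp(rng.normal(0.0, sigma_step.scale))
            if np.log(rng.uniform()) < logpost(prop) - logpost(sigma_e):
                sigma_e = prop
                sigma_step.update(True, adapting)
            else:
                sigma_step.update(False, adapting)

        kept = it - mcmc.warmup
        if kept >= 0 and kept % mcmc.thin == mcmc.thin - 1:
            k = kept // mcmc.thin
            out["lam_slope"][k] = lam_b
            out["mu_slope"][k] = mu_b
            out["lam_intercept"][k] = lam_a
            out["mu_intercept"][k] = mu_a
            out["sigma_e"][k] = sigma_e
            re_a += a
            re_b += b
            if collect:
                ll_store[k] = _pointwise_loglik(data, a, b, sigma_e)

    out["exp_mean_slope"] = -1.0 / out["lam_slope"]
    out["sample_mean_slope"] = out["mu_slope"] - 1.0 / out["lam_slope"]
    out["gauss_var_slope"] = out["sigma_e"] ** 2 * mean_sb_f2
    out["exp_mean_intercept"] = -1.0 / out["lam_intercept"]
    return out, ll_store, re_a / mcmc.draws, re_b / mcmc.draws


# --------------------------------------------------------------------------
# Gaussian-LMM sampler

def _run_gaussian_chain(data, priors, mcmc, chain_seed, collect):
    rng = np.random.default_rng(chain_seed)
    a, b, sigma_e = _ols_start(data)
    sigma_e *= rng.uniform(0.9, 1.1)
    mu_a = float(a.mean())
    mu_b = float(b.mean())
    tau_a = max(float(a.std()), 0.2) * rng.uniform(0.9, 1.1)
    tau_b = max(float(b.std()), 0.05) * rng.uniform(0.9, 1.1)

    sigma_step = _AdaptiveStep(0.02, target=0.35)
    tau_a_step = _AdaptiveStep(0.1, target=0.35)
    tau_b_step = _AdaptiveStep(0.1, target=0.35)

    n_iter = mcmc.warmup + mcmc.draws * mcmc.thin
    out = {
        name: np.empty(mcmc.draws)
        for name in ("mu_slope", "sd_slope", "mu_intercept", "sd_intercept", "sigma_e")
    }
    ll_store = (
        np.empty((mcmc.draws, data.n_obs), dtype=np.float32) if collect else None
    )
    re_a = np.zeros(data.n_eyes)
    re_b = np.zeros(data.n_eyes)

    def _mh_scale(current, step, q, count, prior_scale, rng):
        """MH draw for a SD parameter with Half-Normal(prior_scale) prior."""

        def logpost(s):
            return -(count - 1) * np.log(s) - q / (2 * s**2) - s**2 / (2 * prior_scale**2)

        prop = current * np.exp(rng.normal(0.0, step.scale))
        if np.log(rng.uniform()) < logpost(prop) - logpost(current):
            return prop, True
        return current, False

    for it in range(n_iter):
        adapting = it < mcmc.warmup
        a, b = _bvn_effects_update(
            rng, data, sigma_e,
            np.full(data.n_eyes, mu_a), np.full(data.n_eyes, mu_b),
            np.full(data.n_eyes, tau_a), np.full(data.n_eyes, tau_b),
        )

        prec_b = 1.0 / priors.mu_slope_sd**2 + data.n_eyes / tau_b**2
        mu_b = rng.normal((b.sum() / tau_b**2) / prec_b, 1.0 / np.sqrt(prec_b))
        prec_a = 1.0 / priors.mu_intercept_sd**2 + data.n_eyes / tau_a**2
        mu_a = rng.normal((a.sum() / tau_a**2) / prec_a, 1.0 / np.sqrt(prec_a))

        qb = float(np.sum((b - mu_b) ** 2))
        qa = float(np.sum((a - mu_a) ** 2))
        qr = _rss(data, a, b)
        for _ in range(3):
            tau_b, acc = _mh_scale(
                tau_b, tau_b_step, qb, data.n_eyes, priors.re_slope_sd_scale, rng
            )
            tau_b_step.update(acc, adapting)
            tau_a, acc = _mh_scale(
                tau_a, tau_a_step, qa, data.n_eyes, priors.re_intercept_sd_scale, rng
            )
            tau_a_step.update(acc, adapting)
            sigma_e, acc = _mh_scale(
                sigma_e, sigma_step, qr, data.n_obs, priors.sigma_e_scale, rng
            )
            sigma_step.update(acc, adapting)

        kept = it - mcmc.warmup
        if kept >= 0 and kept % mcmc.thin == mcmc.thin - 1:
            k = kept // mcmc.thin
            out["mu_slope"][k] = mu_b
            out["sd_slope"][k] = tau_b
            out["mu_intercept"][k] = mu_a
            out["sd_intercept"][k] = tau_a
            out["sigma_e"][k] = sigma_e
            re_a += a
            re_b += b
            if collect:
                ll_store[k] = _pointwise_loglik(data, a, b, sigma_e)

    out["sample_mean_slope"] = out["mu_slope"].copy()
    out["var_slope"] = out["sd_slope"] ** 2
    return out, ll_store, re_a / mcmc.draws, re_b / mcmc.draws


# --------------------------------------------------------------------------
# fitting front-ends

_EXG_POP = ("lam_slope", "mu_slope", "lam_intercept", "mu_intercept", "sigma_e")
_GAU_POP = ("mu_slope", "sd_slope", "mu_intercept", "sd_intercept", "sigma_e")


def _diagnose(draws: dict, pop: tuple, mcmc: MCMCConfig) -> tuple[dict, dict]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict({k: draws[k] for k in pop})
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in pop}
    ess = {k: float(ess_ds[k].values) for k in pop}
    return rhat, ess


def _fit(cohort, priors, mcmc, runner, pop, model_name) -> PosteriorSummary:
    data = _EyeData(cohort)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    per_chain = [runner(data, priors, mcmc, s, mcmc.save_loglik) for s in seeds]
    names = per_chain[0][0].keys()
    draws = {k: np.stack([c[0][k] for c in per_chain]) for k in names}
    loglik = (
        np.stack([c[1] for c in per_chain]) if mcmc.save_loglik else None
    )
    re = None
    if mcmc.save_random_effects:
        re = pd.DataFrame(
            {
                "subject_id": data.ids,
                "intercept_mean": np.mean([c[2] for c in per_chain], axis=0),
                "slope_mean": np.mean([c[3] for c in per_chain], axis=0),
            }
        )
    rhat, ess = _diagnose(draws, pop, mcmc)
    result = PosteriorSummary(
        model=model_name,
        draws=draws,
        population_params=pop,
        rhat=rhat,
        ess=ess,
        n_eyes=data.n_eyes,
        n_obs=data.n_obs,
        subject_ids=data.ids,
        log_likelihood=loglik,
        random_effects=re,
    )
    bad_rhat = {k: v for k, v in rhat.items() if v > mcmc.rhat_max}
    bad_ess = {k: v for k, v in ess.items() if v < mcmc.min_ess}
    if bad_rhat or bad_ess:
        msg = (
            f"{model_name} fit failed convergence diagnostics: "
            f"split-Rhat > {mcmc.rhat_max}: {bad_rhat}; ESS < {mcmc.min_ess}: {bad_ess}"
        )
        if mcmc.strict:
            raise ConvergenceError(msg, rhat=rhat)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    return result


def fit_exgauss_lmm(
    cohort: pd.DataFrame,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Fit the exGaussian-LMM to a long-format cohort table.

    Key derived posterior series: ``exp_mean_slope`` (-1/lam, the mean
    "true" rate), ``mu_slope`` (Gaussian/learning mean), ``sample_mean_slope``
    (their sum, the observed mean rate) and ``gauss_var_slope`` (average
    squared expected slope SE).
    """
    return _fit(
        cohort,
        priors or PriorConfig(),
        mcmc or MCMCConfig(),
        _run_exgauss_chain,
        _EXG_POP,
        "exgauss",
    )


def fit_gaussian_lmm(
    cohort: pd.DataFrame,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Fit the reference Gaussian-LMM (independent Gaussian random effects)."""
    return _fit(
        cohort,
        priors or PriorConfig(),
        mcmc or MCMCConfig(),
        _run_gaussian_chain,
        _GAU_POP,
        "gaussian",
    )


# --------------------------------------------------------------------------
# WAIC

def compute_waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from an (n_obs, n_draws) conditional log-likelihood matrix.

    lppd_i = log mean_d exp(l_id); p_i = var_d(l_id); the deviance-scale
    WAIC is -2 * sum_i (lppd_i - p_i) with SE sqrt(n * var_i(pointwise)).
    """
    ll = np.asarray(pointwise_loglik, dtype=np.float64)
    if ll.ndim != 2 or ll.shape[0] < 2 or ll.shape[1] < 2:
        raise DataError("need an (n_obs >= 2, n_draws >= 2) log-likelihood matrix")
    if not np.all(np.isfinite(ll)):
        raise DataError("log-likelihood matrix contains non-finite values")
    n, s = ll.shape
    lppd = special.logsumexp(ll, axis=1) - np.log(s)
    p = ll.var(axis=1, ddof=1)
    pointwise = -2.0 * (lppd - p)
    waic = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=1)))
    return WaicResult(waic=waic, se=se, p_waic=float(p.sum()), pointwise=pointwise)


def compare_waic(loglik_a: np.ndarray, loglik_b: np.ndarray) -> WaicComparison:
    """Paired WAIC comparison of two models over the same observations."""
    ra = compute_waic(loglik_a)
    rb = compute_waic(loglik_b)
    if ra.pointwise.shape != rb.pointwise.shape:
        raise DataError("models must score the same observations")
    d = ra.pointwise - rb.pointwise
    n = d.size
    return WaicComparison(
        result_a=ra,
        result_b=rb,
        difference=float(d.sum()),
        se_difference=float(np.sqrt(n * d.var(ddof=1))),
    )


# --------------------------------------------------------------------------
# p-direction and grouped / trimmed analyses

def p_direction(draws_of_difference) -> float:
    """Two-sided Bayesian p value from the probability of direction.

    pd = max(P(draw > 0), P(draw < 0)); returns 2 * (1 - pd), floored at
    2 / n_draws (an all-one-sided posterior cannot certify a smaller value).
    """
    d = np.asarray(draws_of_difference, dtype=float).reshape(-1)
    if d.size < 1000:
        raise DataError(f"p_direction needs >= 1000 draws, got {d.size}")
    if np.all(d == 0):
        raise DataError("degenerate input: all draws are exactly zero")
    pd_ = max(np.mean(d > 0), np.mean(d < 0))
    return float(max(2.0 * (1.0 - pd_), 2.0 / d.size))


@dataclass
class GroupedResult:
    """Per-group posterior summaries plus draw-wise pairwise comparisons."""

    groups: dict                      # label -> PosteriorSummary
    pairwise: pd.DataFrame            # param, group_a, group_b, mean_diff, p


_GROUP_COMPARE_PARAMS = ("exp_mean_slope", "mu_slope", "sample_mean_slope", "sigma_e")


def fit_grouped(
    cohort: pd.DataFrame,
    groups: dict,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> GroupedResult:
    """Fit the exGaussian-LMM with separate population parameters per group.

    ``groups`` maps subject_id to a label (e.g. the severity classes). Each
    group is sampled with the same chain/draw layout from one spawned seed
    sequence, so draws are aligned and pairwise differences (and their
    p-direction values) can be computed draw-wise.
    """
    mcmc = mcmc or MCMCConfig()
    priors = priors or PriorConfig()
    labels = sorted(set(groups.values()))
    if not labels:
        raise DataError("empty group map")
    member = cohort["subject_id"].map(groups)
    if member.isna().any():
        missing = cohort.loc[member.isna(), "subject_id"].unique()
        raise DataError(f"subjects without a group label: {missing[:5].tolist()}")
    for label in labels:
        n_sub = cohort.loc[member == label, "subject_id"].nunique()
        if n_sub < 20:
            raise DataError(f"group {label!r} has {n_sub} eyes; need >= 20")
    seeds = np.random.SeedSequence(mcmc.seed).spawn(len(labels))
    fits = {}
    for label, seq in zip(labels, seeds):
        sub = cohort[member == label]
        sub_mcmc = replace(mcmc, seed=int(seq.generate_state(1)[0] % (2**31)))
        fits[label] = _fit(
            sub, priors, sub_mcmc, _run_exgauss_chain, _EXG_POP, "exgauss"
        )
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            for param in _GROUP_COMPARE_PARAMS:
                diff = fits[la].stacked(param) - fits[lb].stacked(param)
                rows.append(
                    {
                        "parameter": param,
                        "group_a": la,
                        "group_b": lb,
                        "mean_difference": float(diff.mean()),
                        "p_direction": p_direction(diff),
                    }
                )
    return GroupedResult(groups=fits, pairwise=pd.DataFrame(rows))


def trim_series(cohort: pd.DataFrame, k: int, min_series: int = 10) -> pd.DataFrame:
    """Drop each eye's first ``k`` tests, re-zero time, keep eyes with
    >= ``min_series`` remaining tests."""
    df = cohort.sort_values(["subject_id", "time_years"], kind="stable").copy()
    order = df.groupby("subject_id").cumcount()
    df = df[order >= k]
    sizes = df.groupby("subject_id")["time_years"].transform("size")
    df = df[sizes >= min_series].copy()
    if len(df) == 0:
        raise DataError(f"no eyes have >= {min_series} tests after trimming {k}")
    df["time_years"] = df["time_years"] - df.groupby("subject_id")["time_years"].transform("min")
    df["test_index"] = df.groupby("subject_id").cumcount() + 1
    return df.reset_index(drop=True)


def trimming_analysis(
    cohort: pd.DataFrame,
    max_trim: int,
    min_series: int = 10,
    priors: PriorConfig | None = None,
    mcmc: MCMCConfig | None = None,
) -> pd.DataFrame:
    """Refit the exGaussian-LMM on series trimmed of their first k tests.

    For k = 0..max_trim: drop the first k tests of every eye, re-anchor
    t = 0 at the new first test, drop eyes left with fewer than
    ``min_series`` tests, and refit. A learning effect confined to early
    tests shows up as a Gaussian mean that decays toward zero with k while
    the exponential mean stays put.
    """
    if max_trim < 1:
        raise DataError("max_trim must be >= 1")
    mcmc = mcmc or MCMCConfig()
    base = replace(mcmc, save_loglik=False, save_random_effects=False)
    rows = []
    for k in range(max_trim + 1):
        trimmed = trim_series(cohort, k, min_series=min_series)
        fit = _fit(
            trimmed, priors or PriorConfig(), base, _run_exgauss_chain, _EXG_POP, "exgauss"
        )
        row = {"trim": k, "n_eyes": fit.n_eyes}
        for param, tag in (
            ("exp_mean_slope", "exp_mean"),
            ("mu_slope", "gauss_mean"),
            ("sample_mean_slope", "sample_mean"),
        ):
            lo, hi = fit.ci(param)
            row[tag] = fit.mean(param)
            row[f"{tag}_lo"] = lo
            row[f"{tag}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)
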