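"""Sign-reversed exponentially modified Gaussian (exGaussian) distribution.

The rate of progression (RoP) of the visual-field mean deviation is modelled
as the sum of two independent components,

    X = -E + G,     E ~ Exponential(lam),   G ~ Normal(mu, sigma**2),

i.e. a "true" rate drawn from a reflected exponential (disease only worsens,
so the true rate is <= 0) plus Gaussian measurement noise / learning offset.
The resulting density is the convolution of the two component densities — an
exGaussian with its exponential tail pointing toward negative values.

All densities are evaluated through the log-space complementary-normal form
(``scipy.special.log_ndtr``) so that large ``lam * sigma`` does not overflow
the naive ``exp(...) * Phi(...)`` expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .exceptions import ParameterError

__all__ = ["ExGaussParams", "exgauss_pdf", "exgauss_cdf", "exgauss_moments", "exgauss_sample"]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class ExGaussParams:
    """Parameters of the sign-reversed exGaussian RoP distribution.

    Attributes
    ----------
    lam
        Rate of the exponential component, (dB/year)^-1, strictly positive.
        The exponential-component mean is ``-1/lam`` (negative by construction).
    mu
        Mean of the Gaussian component, dB/year.
    sigma
        Standard deviation of the Gaussian component, dB/year, non-negative.
        ``sigma == 0`` degenerates to a reflected, shifted exponential.
    """

    lam: float
    mu: float = 0.0
    sigma: float = 1.0

    def __post_init__(self):
        for name in ("lam", "mu", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
        if self.lam <= 0:
            raise ParameterError(f"lam must be strictly positive, got {self.lam}")
        if self.sigma < 0:
            raise ParameterError(f"sigma must be non-negative, got {self.sigma}")

    @property
    def mean(self) -> float:
        return self.mu - 1.0 / self.lam

    @property
    def variance(self) -> float:
        return self.sigma**2 + 1.0 / self.lam**2


def _as_params(params: ExGaussParams) -> ExGaussParams:
    if not isinstance(params, ExGaussParams):
        raise ParameterError(f"expected ExGaussParams, got {type(params).__name__}")
    return params


def exgauss_pdf(x, params: ExGaussParams):
    """Probability density of the sign-reversed exGaussian at ``x`` (dB/year).

    For sigma > 0 the density is evaluated as

        f(x) = (lam/2) * exp(lam*(x - mu) + lam^2 sigma^2 / 2)
                       * erfc((x - mu + lam sigma^2) / (sqrt(2) sigma))

    with the erfc factor computed through ``log_ndtr`` for stability.
    """
    p = _as_params(params)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("x must be finite")
    if p.sigma == 0.0:
        # exact reflected exponential: X = mu - E
        with np.errstate(over="ignore"):
            out = np.where(x <= p.mu, p.lam * np.exp(p.lam * (x - p.mu)), 0.0)
        return out if out.ndim else float(out)
    z = (x - p.mu) / p.sigma
    ls = p.lam * p.sigma
    # log erfc(u) = log 2 + log Phi(-u*sqrt(2)); here u = (z + ls)/sqrt(2)
    log_tail = _LOG2 + special.log_ndtr(-(z + ls))
    log_pdf = np.log(p.lam) - _LOG2 + ls * z + 0.5 * ls**2 + log_tail
    out = np.exp(log_pdf)
    return out if out.ndim else float(out)


def exgauss_cdf(x, params: ExGaussParams):
    """Cumulative distribution function P(X <= x) of the sign-reversed exGaussian."""
    p = _as_params(params)
    x = np.asarray(x, dtype=float)
    if p.sigma == 0.0:
        with np.errstate(over="ignore"):
            out = np.where(x <= p.mu, np.exp(p.lam * np.minimum(x - p.mu, 0.0)), 1.0)
        return out if out.ndim else float(out)
    z = (x - p.mu) / p.sigma
    ls = p.lam * p.sigma
    # With Y = E + G', G' ~ N(-mu, sigma^2): P(X <= x) = P(Y >= -x), which
    # reduces to  Phi(z) + exp(ls*z + ls^2/2 + log Phi(-(z + ls)))
    # (the sigma -> 0 limit recovers exp(lam*(x - mu)) for x < mu).
    log_term = ls * z + 0.5 * ls**2 + special.log_ndtr(-(z + ls))
    out = special.ndtr(z) + np.exp(log_term)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def exgauss_moments(params: ExGaussParams) -> tuple[float, float]:
    """Mean and variance of the distribution.

    Component means and variances add: mean = mu - 1/lam,
    variance = sigma**2 + 1/lam**2.
    """
    p = _as_params(params)
    return p.mean, p.variance


def exgauss_sample(n: int, params: ExGaussParams, seed) -> np.ndarray:
    """Draw ``n`` reproducible samples as -Exponential(lam) + Normal(mu, sigma).

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    p = _as_params(params)
    if int(n) < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = -rng.exponential(1.0 / p.lam, size=int(n))
    if p.sigma > 0 or p.mu != 0.0:
        draws = draws + rng.normal(p.mu, p.sigma, size=int(n))
    return draws
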