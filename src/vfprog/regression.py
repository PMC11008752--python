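"""Per-eye ordinary least squares utilities.

Each visual-field series is summarized by a simple linear regression of MD
(dB) on time (years from the first test). The residual standard error
(``resid_se``, n-2 denominator) is the unbiased estimate of the per-eye test
variability, and the schedule-determined standard errors

    se_slope     = sigma_e / sqrt(S_tt),          S_tt = sum (t - tbar)^2
    se_intercept = sigma_e * sqrt(1/n + tbar^2 / S_tt)

are the Gaussian-noise SDs that the hierarchical model attaches to each
random slope and intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import special

from .exceptions import DataError, ScheduleError

__all__ = [
    "SubjectSummary",
    "fit_series_ols",
    "expected_slope_se",
    "expected_intercept_se",
    "summarize_cohort",
    "empirical_cdf",
    "ks_test",
]


@dataclass(frozen=True)
class SubjectSummary:
    """OLS summary of one eye's MD series."""

    subject_id: object
    n_tests: int
    slope: float          # dB/year
    intercept: float      # dB, modelled MD at t = 0 (first test)
    resid_se: float       # dB, sqrt(RSS / (n - 2))
    s_tt: float           # years^2, sum of squared centred times
    t_bar: float          # years
    se_slope: float       # dB/year
    se_intercept: float   # dB

    def as_dict(self) -> dict:
        return asdict(self)


def _check_schedule(times: np.ndarray, min_n: int = 3) -> None:
    if times.size < min_n:
        raise DataError(f"need at least {min_n} observations, got {times.size}")
    if np.ptp(times) == 0:
        raise ScheduleError("degenerate schedule: all test times are equal")


def fit_series_ols(times, md, subject_id=None) -> SubjectSummary:
    """Fit MD ~ time by OLS for a single series.

    Requires >= 3 observations (so the residual SE has at least one degree
    of freedom) and at least two distinct times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(md, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise DataError("times and md must be 1-D sequences of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise DataError("times and md must be finite")
    _check_schedule(t)
    n = t.size
    t_bar = t.mean()
    tc = t - t_bar
    s_tt = float(tc @ tc)
    slope = float(tc @ y) / s_tt
    intercept = float(y.mean() - slope * t_bar)
    resid = y - intercept - slope * t
    resid_se = float(np.sqrt((resid @ resid) / (n - 2)))
    return SubjectSummary(
        subject_id=subject_id,
        n_tests=int(n),
        slope=slope,
        intercept=intercept,
        resid_se=resid_se,
        s_tt=s_tt,
        t_bar=float(t_bar),
        se_slope=resid_se / np.sqrt(s_tt),
        se_intercept=resid_se * np.sqrt(1.0 / n + t_bar**2 / s_tt),
    )


def expected_slope_se(schedule, sigma_e: float):
    """Expected SE of the OLS slope for a schedule and residual SD sigma_e."""
    t = np.asarray(schedule, dtype=float)
    _check_schedule(t)
    if sigma_e < 0:
        raise DataError("sigma_e must be non-negative")
    tc = t - t.mean()
    return float(sigma_e / np.sqrt(tc @ tc))


def expected_intercept_se(schedule, sigma_e: float):
    """Expected SE of the OLS intercept (time origin at the schedule's zero)."""
    t = np.asarray(schedule, dtype=float)
    _check_schedule(t)
    if sigma_e < 0:
        raise DataError("sigma_e must be non-negative")
    tc = t - t.mean()
    return float(sigma_e * np.sqrt(1.0 / t.size + t.mean() ** 2 / (tc @ tc)))


def summarize_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-eye OLS summaries of a long-format cohort table.

    Expects columns ``subject_id, time_years, md_db``; returns one row per
    eye with the :class:`SubjectSummary` fields.
    """
    for col in ("subject_id", "time_years", "md_db"):
        if col not in cohort.columns:
            raise DataError(f"cohort table is missing column {col!r}")
    rows = []
    for sid, grp in cohort.groupby("subject_id", sort=True):
        rows.append(
            fit_series_ols(grp["time_years"].to_numpy(), grp["md_db"].to_numpy(), sid).as_dict()
        )
    return pd.DataFrame(rows)


class ECDF:
    """Right-continuous empirical CDF with jump points and probabilities."""

    def __init__(self, values):
        v = np.asarray(values, dtype=float)
        if v.size == 0:
            raise DataError("empirical_cdf requires at least one value")
        if not np.all(np.isfinite(v)):
            raise DataError("empirical_cdf requires finite values")
        self.n = v.size
        self.x, counts = np.unique(v, return_counts=True)
        self.p = np.cumsum(counts) / self.n

    def __call__(self, x):
        idx = np.searchsorted(self.x, np.asarray(x, dtype=float), side="right")
        out = np.where(idx > 0, self.p[np.maximum(idx - 1, 0)], 0.0)
        return out if out.ndim else float(out)


def empirical_cdf(values) -> ECDF:
    """Empirical CDF of ``values`` as a callable step function (rank / n)."""
    return ECDF(values)


def ks_test(values, cdf) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of ``values`` against ``cdf``.

    D is the sup-distance evaluated at both limits of every jump of the
    empirical CDF; the p value uses the asymptotic Kolmogorov distribution.
    No correction is made for parameters estimated from the same data.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise DataError(f"ks_test requires at least 10 values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise DataError("ks_test requires finite values")
    v = np.sort(v)
    n = v.size
    f = np.asarray(cdf(v), dtype=float)
    if not np.all(np.isfinite(f)):
        raise DataError("cdf returned non-finite values")
    upper = np.arange(1, n + 1) / n - f       # ECDF from above
    lower = f - np.arange(0, n) / n           # ECDF from below
    d = float(max(upper.max(), lower.max(), 0.0))
    p = float(special.kolmogorov(d * np.sqrt(n)))
    return d, min(max(p, 0.0), 1.0)
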