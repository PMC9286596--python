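"""Standardized Precipitation-Evapotranspiration Index (SPEI).

The SPEI standardizes the climatic water balance D = P - PET accumulated
over a trailing window of ``scale_months`` months. For every calendar
month and pixel, a three-parameter log-logistic distribution is fitted to
the accumulated balance over a reference period using probability-weighted
moments (PWM); the fitted CDF value is then mapped through the standard
normal quantile function, so an SPEI of -1 means the accumulation sits one
"standard" step into the dry tail of that pixel's climatology.

Conventions:

* The accumulation window for month ``m`` ends with month ``m - 1``, so
  the index labelled for a month describes strictly antecedent conditions.
* Degenerate fits (constant balance, invalid shape parameter) are marked
  undefined and transform to NaN rather than a fabricated value.
* The CDF is clipped to [1e-4, 1 - 1e-4] before the normal quantile, which
  bounds SPEI at roughly +/-3.7 and keeps values finite outside the fitted
  support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma as _gamma
from scipy.stats import norm

_CDF_EPS = 1e-4


@dataclass
class SpeiFit:
    """Per-pixel, per-calendar-month log-logistic parameters.

    Arrays have shape ``(12, n_rows, n_cols)`` indexed by calendar month - 1.
    ``alpha`` is the scale (> 0 where defined), ``beta`` the shape and
    ``gamma`` the location parameter of the fitted distribution.
    """

    scale_months: int
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    defined: np.ndarray
    reference_years: tuple[int, ...]


def water_balance(precip_by_month: dict[tuple[int, int], np.ndarray],
                  pet_by_month: dict[tuple[int, int], np.ndarray],
                  ) -> dict[tuple[int, int], np.ndarray]:
    """Monthly climatic water balance D = P - PET, keyed by (year, month)."""
    out = {}
    for key, p in precip_by_month.items():
        if key not in pet_by_month:
            raise ValueError(f"PET series missing month {key}")
        out[key] = np.asarray(p, dtype=float) - np.asarray(pet_by_month[key], dtype=float)
    return out


def _previous_months(year: int, month: int, k: int) -> list[tuple[int, int]]:
    """The k months strictly before (year, month), oldest first."""
    ym = year * 12 + (month - 1)
    return [((ym - i) // 12, (ym - i) % 12 + 1) for i in range(k, 0, -1)]


def accumulate_balance(d_by_month: dict[tuple[int, int], np.ndarray],
                       scale_months: int,
                       ) -> dict[tuple[int, int], np.ndarray]:
    """Trailing-window sums of the water balance.

    The sum labelled (year, month) covers the ``scale_months`` months
    ending with the month before it; months whose window reaches past the
    start of the series are omitted (undefined).
    """
    out = {}
    for (year, month) in d_by_month:
        window = _previous_months(year, month, scale_months)
        if all(w in d_by_month for w in window):
            out[(year, month)] = np.sum([d_by_month[w] for w in window], axis=0)
    return out


def _pwm_loglogistic(samples: np.ndarray):
    """PWM fit of the 3-parameter log-logistic, vectorized over pixels.

    ``samples`` has shape (n, ...) with n observations per pixel. Returns
    (alpha, beta, gamma, defined). Uses the plotting-position-free PWM
    estimators w_s = n^-1 sum_i x_(i) * C(n-i, s)/C(n-1, s) on the
    ascending order statistics.
    """
    x = np.sort(np.asarray(samples, dtype=float), axis=0)
    n = x.shape[0]
    if n < 4:
        raise ValueError("need at least 4 observations per pixel for the PWM fit")
    i = np.arange(1, n + 1).reshape((n,) + (1,) * (x.ndim - 1))
    w0 = x.mean(axis=0)
    w1 = (x * (n - i) / (n - 1)).sum(axis=0) / n
    w2 = (x * (n - i) * (n - i - 1) / ((n - 1) * (n - 2))).sum(axis=0) / n

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (2 * w1 - w0) / (6 * w1 - w0 - 6 * w2)
        g = _gamma(1 + 1 / beta) * _gamma(1 - 1 / beta)
        alpha = (w0 - 2 * w1) * beta / g
        gamma_loc = w0 - alpha * g
    defined = np.isfinite(beta) & (beta > 1.0) & np.isfinite(alpha) & (alpha > 0)
    alpha = np.where(defined, alpha, np.nan)
    beta = np.where(defined, beta, np.nan)
    gamma_loc = np.where(defined, gamma_loc, np.nan)
    return alpha, beta, gamma_loc, defined


def fit_spei(precip_by_month: dict[tuple[int, int], np.ndarray],
             pet_by_month: dict[tuple[int, int], np.ndarray],
             scale_months: int,
             reference_years: tuple[int, ...] | None = None) -> SpeiFit:
    """Fit the accumulation distribution per pixel and calendar month.

    ``reference_years`` defaults to every year with a defined accumulation
    for the given calendar month. Around 15+ years of monthly data are
    recommended for a stable fit; fewer are accepted (down to 4) with
    noisier, possibly undefined, parameters.
    """
    d = water_balance(precip_by_month, pet_by_month)
    acc = accumulate_balance(d, scale_months)
    shape = next(iter(d.values())).shape
    alpha = np.full((12,) + shape, np.nan)
    beta = np.full((12,) + shape, np.nan)
    gamma_loc = np.full((12,) + shape, np.nan)
    defined = np.zeros((12,) + shape, dtype=bool)
    years_used: set[int] = set()
    for month in range(1, 13):
        years = sorted(y for (y, m) in acc if m == month
                       and (reference_years is None or y in reference_years))
        if len(years) < 4:
            continue
        years_used.update(years)
        samples = np.stack([acc[(y, month)] for y in years], axis=0)
        a, b, g, ok = _pwm_loglogistic(samples)
        alpha[month - 1], beta[month - 1], gamma_loc[month - 1] = a, b, g
        defined[month - 1] = ok
    return SpeiFit(scale_months=scale_months, alpha=alpha, beta=beta,
                   gamma=gamma_loc, defined=defined,
                   reference_years=tuple(sorted(years_used)))


def spei_transform(d_accumulated: np.ndarray, fit: SpeiFit,
                   calendar_month: int) -> np.ndarray:
    """Map an accumulated balance to the standard-normal SPEI scale.

    Monotone non-decreasing in the input; NaN where the fit is undefined.
    """
    m = calendar_month - 1
    x = np.asarray(d_accumulated, dtype=float)
    alpha, beta, gamma_loc = fit.alpha[m], fit.beta[m], fit.gamma[m]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = x - gamma_loc
        cdf = np.where(z > 0, 1.0 / (1.0 + (alpha / z) ** beta), 0.0)
    cdf = np.clip(cdf, _CDF_EPS, 1 - _CDF_EPS)
    out = norm.ppf(cdf)
    out[~fit.defined[m]] = np.nan
    out[~np.isfinite(x)] = np.nan
    return out


def spei_series(precip_by_month: dict[tuple[int, int], np.ndarray],
                pet_by_month: dict[tuple[int, int], np.ndarray],
                scale_months: int,
                reference_years: tuple[int, ...] | None = None,
                ) -> tuple[dict[tuple[int, int], np.ndarray], SpeiFit]:
    """Convenience: fit on the reference period, transform every month."""
    fit = fit_spei(precip_by_month, pet_by_month, scale_months, reference_years)
    acc = accumulate_balance(water_balance(precip_by_month, pet_by_month),
                             scale_months)
    series = {ym: spei_transform(a, fit, ym[1]) for ym, a in acc.items()}
    return series, fit
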