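"""Poisson risk inference from predicted expected counts.

Given the expected count lambda over the study period, the count follows a
Poisson law, so

* P(at least one case) = 1 - exp(-lambda),
* odds of at least one case vs none = exp(lambda) - 1,

and a village is flagged a hotspot when its odds exceed a threshold
(default 500, i.e. lambda > ln 501 ≈ 6.22).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "poisson_pmf",
    "prob_at_least_one",
    "odds_ntd",
    "fit_poisson_moments",
    "make_risk_report",
]


def _check_nonneg(value, name: str):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


def poisson_pmf(k, lam):
    """P(K = k) = lambda^k exp(-lambda) / k!, evaluated in log space."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0) or np.any(k_arr != np.floor(k_arr)):
        raise ValueError("k must be a nonnegative integer")
    lam = _check_nonneg(lam, "lambda")
    out = stats.poisson.pmf(k_arr, lam)
    return float(out) if np.isscalar(k) and np.ndim(lam) == 0 else out


def prob_at_least_one(lam):
    """P(K >= 1) = 1 - exp(-lambda)."""
    lam = _check_nonneg(lam, "lambda")
    out = -np.expm1(-lam)
    return float(out) if np.ndim(out) == 0 else out


def odds_ntd(lam):
    """Odds of at least one case against none: 1/P(K=0) - 1 = exp(lambda) - 1."""
    lam = _check_nonneg(lam, "lambda")
    out = np.expm1(lam)
    return float(out) if np.ndim(out) == 0 else out


def fit_poisson_moments(counts) -> dict:
    """Sample Poisson moment fit plus an overdispersion score test.

    Returns mean, variance (ddof=1) and a variance-vs-mean score statistic

        z = sum((y - ybar)^2 - y) / sqrt(2 * n * ybar^2)

    which is asymptotically standard normal under the Poisson null, with a
    one-sided (overdispersion) p-value.  This is the package's
    interpretation of a dispersion diagnostic; it is a standard score test,
    not a reproduction of any particular published statistic.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two counts")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be nonnegative integers")
    mean = float(counts.mean())
    var = float(counts.var(ddof=1))
    n = counts.size
    if mean > 0:
        z = float(np.sum((counts - mean) ** 2 - counts) / np.sqrt(2 * n * mean**2))
        p = float(stats.norm.sf(z))
    else:
        z, p = np.nan, np.nan
    return {"mean": mean, "variance": var, "dispersion_stat": z, "p_value": p}


def make_risk_report(lambda_hat, odds_threshold: float = 500.0, ids=None) -> pd.DataFrame:
    """Per-site risk table: lambda, P(>=1 case), odds, hotspot flag."""
    lam = np.asarray(lambda_hat, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lambda_hat must be strictly positive")
    p1 = prob_at_least_one(lam)
    odds = odds_ntd(lam)
    return pd.DataFrame(
        {
            "id": np.arange(len(lam)) if ids is None else np.asarray(ids),
            "lambda_hat": lam,
            "p_ge1": p1,
            "odds": odds,
            "hotspot": odds > odds_threshold,
        }
    )
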