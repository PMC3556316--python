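"""Variogram models, empirical estimators, WLS fitting and field simulation.

The residual structure of the disease-count model is described by classical
bounded variogram families.  A model is parameterised by a nugget (the
discontinuity at the origin, absorbing measurement/Poisson noise), a partial
sill (the variance of the spatially structured component) and a range (the
separation, in metres, at which the structured correlation has effectively
vanished).  For the unbounded-support families (exponential, gaussian,
stable) the range is the *effective* range: correlation exp(-3) ≈ 0.05 at
``h = range_m``, the convention used by most GIS packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist, squareform

FAMILIES = ("spherical", "circular", "exponential", "gaussian", "stable")

__all__ = [
    "FAMILIES",
    "VariogramModel",
    "EmpiricalVariogram",
    "empirical_variogram",
    "empirical_cross_variogram",
    "fit_variogram",
    "covariance_matrix",
    "simulate_gaussian_field",
    "simulate_correlated_pair",
    "mean_nn_distance",
]


def _correlation(family: str, h: np.ndarray, range_m: float, exponent: float) -> np.ndarray:
    """Correlation function rho(h) with rho(0)=1 for the structured part."""
    h = np.asarray(h, dtype=float)
    u = h / range_m
    if family == "spherical":
        rho = np.where(u < 1.0, 1.0 - 1.5 * u + 0.5 * u**3, 0.0)
    elif family == "circular":
        uc = np.clip(u, 0.0, 1.0)
        rho = np.where(
            u < 1.0,
            1.0 - (2.0 / np.pi) * (uc * np.sqrt(1.0 - uc**2) + np.arcsin(uc)),
            0.0,
        )
    elif family == "exponential":
        rho = np.exp(-3.0 * u)
    elif family == "gaussian":
        rho = np.exp(-3.0 * u**2)
    elif family == "stable":
        rho = np.exp(-3.0 * u**exponent)
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    return rho


@dataclass(frozen=True)
class VariogramModel:
    """Isotropic variogram model gamma(h) = nugget + partial_sill * (1 - rho(h))."""

    family: str
    nugget: float
    partial_sill: float
    range_m: float
    stable_exponent: float = 1.5

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be nonnegative")
        if self.range_m <= 0:
            raise ValueError("range_m must be positive")
        if self.family == "stable" and not (0 < self.stable_exponent <= 2):
            raise ValueError("stable_exponent must lie in (0, 2]")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    def semivariance(self, h) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        rho = _correlation(self.family, h, self.range_m, self.stable_exponent)
        gamma = self.partial_sill * (1.0 - rho)
        # nugget is a discontinuity: gamma(0) = 0 exactly
        return np.where(h > 0, gamma + self.nugget, 0.0)

    def covariance(self, h) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h); C(0) includes the nugget."""
        h = np.asarray(h, dtype=float)
        rho = _correlation(self.family, h, self.range_m, self.stable_exponent)
        return self.partial_sill * rho + np.where(h > 0, 0.0, self.nugget)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "nugget": float(self.nugget),
            "partial_sill": float(self.partial_sill),
            "range_m": float(self.range_m),
        }
        if self.family == "stable":
            d["stable_exponent"] = float(self.stable_exponent)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariogramModel":
        return cls(
            family=d["family"],
            nugget=float(d["nugget"]),
            partial_sill=float(d["partial_sill"]),
            range_m=float(d["range_m"]),
            stable_exponent=float(d.get("stable_exponent", 1.5)),
        )


@dataclass
class EmpiricalVariogram:
    """Binned Matheron (or cross) variogram estimate."""

    bin_centers: np.ndarray
    gamma: np.ndarray
    counts: np.ndarray
    lag_size: float
    cross: bool = False


def mean_nn_distance(coords: np.ndarray) -> float:
    """Mean nearest-neighbour distance; the default lag size."""
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def _bin_pairs(coords: np.ndarray, lag_size: float, n_lags: int):
    """Upper-triangle pair indices and their lag-bin index (-1 = beyond last bin)."""
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(coords[iu, 0] - coords[ju, 0], coords[iu, 1] - coords[ju, 1])
    b = np.floor(d / lag_size).astype(int)
    b[b >= n_lags] = -1
    return iu, ju, b


def empirical_variogram(
    values,
    coords,
    lag_size: float | None = None,
    n_lags: int = 12,
) -> EmpiricalVariogram:
    """Matheron estimator gamma(h) = (1/2N(h)) * sum (z_i - z_j)^2 per lag bin.

    Bins with zero pairs are omitted.  ``lag_size`` defaults to the mean
    nearest-neighbour distance of the site configuration.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two sites")
    if np.allclose(pdist(coords), 0):
        raise ValueError("all sites coincident; variogram undefined")
    if lag_size is None:
        lag_size = mean_nn_distance(coords)
    if lag_size <= 0:
        raise ValueError("lag_size must be positive")
    iu, ju, b = _bin_pairs(coords, lag_size, n_lags)
    return _bin_semivariance(values, values, iu, ju, b, lag_size, n_lags, cross=False)


def empirical_cross_variogram(
    values_a,
    values_b,
    coords,
    lag_size: float | None = None,
    n_lags: int = 12,
) -> EmpiricalVariogram:
    """Cross-variogram (1/2N(h)) * sum (a_i - a_j)(b_i - b_j) per lag bin."""
    values_a = np.asarray(values_a, dtype=float)
    values_b = np.asarray(values_b, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if lag_size is None:
        lag_size = mean_nn_distance(coords)
    iu, ju, b = _bin_pairs(coords, lag_size, n_lags)
    return _bin_semivariance(values_a, values_b, iu, ju, b, lag_size, n_lags, cross=True)


def _bin_semivariance(va, vb, iu, ju, b, lag_size, n_lags, cross):
    ok = b >= 0
    prod = 0.5 * (va[iu[ok]] - va[ju[ok]]) * (vb[iu[ok]] - vb[ju[ok]])
    counts = np.bincount(b[ok], minlength=n_lags)
    sums = np.bincount(b[ok], weights=prod, minlength=n_lags)
    nonempty = counts > 0
    centers = (np.arange(n_lags) + 0.5) * lag_size
    return EmpiricalVariogram(
        bin_centers=centers[nonempty],
        gamma=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
        lag_size=float(lag_size),
        cross=cross,
    )


def fit_variogram(
    empirical: EmpiricalVariogram,
    family: str = "spherical",
    fit_exponent: bool = True,
    full_output: bool = False,
):
    """Weighted least-squares fit of a theoretical model to a binned variogram.

    Weights are ``pair_count / h**2``, down-weighting sparse and distant bins.
    A flat empirical variogram (no resolvable structure) is fitted as a pure
    plateau — partial sill at the common level, range pinned at the largest
    lag — and flagged in ``info['flat']`` when ``full_output`` is requested.
    """
    h = np.asarray(empirical.bin_centers, dtype=float)
    g = np.asarray(empirical.gamma, dtype=float)
    w = np.sqrt(np.asarray(empirical.counts, dtype=float)) / h
    if len(h) < 3:
        raise ValueError("need at least three nonempty lag bins to fit a variogram")
    flags: dict = {"flat": False}

    gmax = float(g.max())
    if gmax <= 0 or np.ptp(g) < 1e-12 * max(gmax, 1.0):
        # degenerate plateau: no structure to resolve
        model = VariogramModel(
            family=family,
            nugget=0.0,
            partial_sill=max(gmax, 0.0) or 1e-12,
            range_m=float(h.max()),
            stable_exponent=2.0 if family == "gaussian" else 1.5,
        )
        flags["flat"] = True
        return (model, {"wrss": 0.0, **flags}) if full_output else model

    hmax = float(h.max())
    sill0 = float(np.mean(g[-max(2, len(g) // 3):]))
    nug0 = float(np.clip(g[0], 0.0, sill0))
    # first lag where gamma reaches 95% of the plateau
    above = np.nonzero(g >= 0.95 * sill0)[0]
    rng0 = float(h[above[0]]) if len(above) else hmax
    rng0 = float(np.clip(rng0, h[0], 2 * hmax))

    fit_exp = family == "stable" and fit_exponent

    def unpack(p):
        nug, psill, rng = p[0], p[1], p[2]
        expo = p[3] if fit_exp else (2.0 if family == "gaussian" else 1.5)
        return nug, psill, rng, expo

    def resid(p):
        nug, psill, rng, expo = unpack(p)
        rho = _correlation(family, h, rng, expo)
        return w * (nug + psill * (1.0 - rho) - g)

    # range capped slightly beyond the observed lag span: an empirical
    # variogram still climbing at hmax cannot identify a longer range anyway,
    # and an uncapped fit can run away and destabilise kriging downstream
    x0 = [nug0, max(sill0 - nug0, 1e-6 * sill0), min(rng0, 1.2 * hmax)]
    lo = [0.0, 0.0, h[0] * 1e-3]
    hi = [2 * gmax, 4 * gmax, 1.5 * hmax]
    if fit_exp:
        x0.append(1.5)
        lo.append(0.05)
        hi.append(2.0)
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
    nug, psill, rng, expo = unpack(sol.x)
    model = VariogramModel(
        family=family,
        nugget=float(nug),
        partial_sill=float(max(psill, 1e-12)),
        range_m=float(rng),
        stable_exponent=float(expo),
    )
    if full_output:
        return model, {"wrss": float(np.sum(sol.fun**2)), **flags}
    return model


def covariance_matrix(coords, model: VariogramModel) -> np.ndarray:
    """Site-by-site covariance implied by the variogram: sill - gamma(h)."""
    coords = np.asarray(coords, dtype=float)
    d = squareform(pdist(coords))
    c = model.partial_sill * _correlation(model.family, d, model.range_m, model.stable_exponent)
    c[np.eye(len(coords), dtype=bool)] = model.sill
    return c


def _chol_with_jitter(c: np.ndarray) -> np.ndarray:
    scale = max(float(np.trace(c)) / max(len(c), 1), 1.0)
    for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.cholesky(c + jitter * scale * np.eye(len(c)))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance matrix not positive semidefinite even after jitter up to 1e-6"
    )


def simulate_gaussian_field(
    coords,
    model: VariogramModel,
    rng: np.random.Generator | int,
    n_draws: int = 1,
) -> np.ndarray:
    """Exact (Cholesky) draws of a zero-mean Gaussian field at the sites.

    Returns shape ``(n,)`` for ``n_draws == 1`` else ``(n_draws, n)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if model.sill == 0:
        out = np.zeros((n_draws, n))
        return out[0] if n_draws == 1 else out
    L = _chol_with_jitter(covariance_matrix(coords, model))
    z = rng.standard_normal((n_draws, n))
    out = z @ L.T
    return out[0] if n_draws == 1 else out


def simulate_correlated_pair(
    coords,
    model_a: VariogramModel,
    model_b: VariogramModel,
    cross_corr: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """One draw of two cross-correlated zero-mean fields with exact marginals.

    Construction: ``a = L_a z1``, ``b = L_b (rho z1 + sqrt(1-rho^2) z2)`` with
    ``L`` the Cholesky factors of the two direct covariances — a valid joint
    Gaussian for any ``rho`` in [-1, 1]; with identical models and ``rho = 1``
    the two draws coincide.
    """
    if not -1.0 <= cross_corr <= 1.0:
        raise ValueError("cross_corr must lie in [-1, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    zb = cross_corr * z1 + math.sqrt(max(1.0 - cross_corr**2, 0.0)) * z2

    def draw(model, z):
        if model.sill == 0:
            return np.zeros(n)
        return _chol_with_jitter(covariance_matrix(coords, model)) @ z

    return draw(model_a, z1), draw(model_b, zb)
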