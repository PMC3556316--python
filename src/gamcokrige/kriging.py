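"""Residual definitions, coregionalization fitting and cokriging.

After the additive model supplies local means, two residual series are
formed on the count scale:

* spatial residual  eps_s(i) = observed count - fitted local mean;
* regional residual eps_r(i) = observed count - mean of all observed counts.

The spatial residual at an unsampled (or held-out) location is then
predicted by cokriging: a best linear predictor combining eps_s and eps_r at
the nearest neighbours, with weights derived from a linear model of
coregionalization (LMC).  The LMC represents both direct variograms and the
cross-variogram as combinations of shared structures (a nugget plus a
short-range "local" and a long-range "regional" structure), so the joint
covariance used by the solver is positive semidefinite by construction once
each structure's 2x2 coefficient matrix is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .variograms import (
    EmpiricalVariogram,
    VariogramModel,
    _correlation,
    empirical_cross_variogram,
    empirical_variogram,
    fit_variogram,
    mean_nn_distance,
)

__all__ = [
    "ResidualSet",
    "Structure",
    "CoregionalizationModel",
    "CokrigeResult",
    "compute_residuals",
    "fit_lmc",
    "cokrige",
    "ordinary_kriging",
    "ResidualCokriger",
]


@dataclass
class ResidualSet:
    """Spatial (local) and regional residual vectors at the sites."""

    spatial: np.ndarray
    regional: np.ndarray

    def __post_init__(self) -> None:
        self.spatial = np.asarray(self.spatial, dtype=float)
        self.regional = np.asarray(self.regional, dtype=float)
        if self.spatial.shape != self.regional.shape:
            raise ValueError("residual vectors must have equal length")


def compute_residuals(counts, fitted_means) -> ResidualSet:
    """eps_s = count - fitted mean; eps_r = count - regional mean (mean-zero)."""
    counts = np.asarray(counts, dtype=float)
    fitted = np.asarray(fitted_means, dtype=float)
    return ResidualSet(spatial=counts - fitted, regional=counts - counts.mean())


# --------------------------------------------------------------------- LMC
@dataclass(frozen=True)
class Structure:
    """One elementary structure of the LMC: nugget or a correlated component."""

    family: str  # "nugget" or a variogram family
    range_m: float = 1.0
    exponent: float = 1.5

    def correlation(self, h: np.ndarray) -> np.ndarray:
        if self.family == "nugget":
            return np.where(np.asarray(h, dtype=float) > 0, 0.0, 1.0)
        return _correlation(self.family, h, self.range_m, self.exponent)

    def variogram_part(self, h: np.ndarray) -> np.ndarray:
        if self.family == "nugget":
            return np.where(np.asarray(h, dtype=float) > 0, 1.0, 0.0)
        return 1.0 - _correlation(self.family, h, self.range_m, self.exponent)


@dataclass
class CoregionalizationModel:
    """LMC for (eps_s, eps_r): shared structures with 2x2 coefficient matrices.

    ``b_matrices[k]`` is the symmetric coefficient matrix of structure ``k``
    (order: [spatial, regional]).  ``direct_local`` / ``direct_regional`` are
    the single-structure variogram models fitted marginally to each residual
    series, retained for reporting; the solver uses the structures.
    """

    structures: list[Structure]
    b_matrices: list[np.ndarray]
    direct_local: VariogramModel
    direct_regional: VariogramModel
    psd_flag: bool = False  # True when a cross coefficient had to be clipped

    def __post_init__(self) -> None:
        if len(self.structures) != len(self.b_matrices):
            raise ValueError("one coefficient matrix per structure required")
        for b in self.b_matrices:
            b = np.asarray(b, dtype=float)
            if b.shape != (2, 2) or not np.allclose(b, b.T):
                raise ValueError("coefficient matrices must be symmetric 2x2")

    def covariance(self, h, a: int, b: int) -> np.ndarray:
        """C_ab(h) = sum_k B_k[a,b] * rho_k(h)."""
        h = np.asarray(h, dtype=float)
        out = np.zeros_like(h, dtype=float)
        for s, bm in zip(self.structures, self.b_matrices):
            out += bm[a, b] * s.correlation(h)
        return out

    @property
    def sill_matrix(self) -> np.ndarray:
        return np.sum(self.b_matrices, axis=0)

    @property
    def cross_correlation(self) -> float:
        s = self.sill_matrix
        denom = np.sqrt(s[0, 0] * s[1, 1])
        return float(s[0, 1] / denom) if denom > 0 else 0.0

    def to_dict(self) -> dict:
        return {
            "structures": [
                {"family": s.family, "range_m": s.range_m, "exponent": s.exponent}
                for s in self.structures
            ],
            "b_matrices": [np.asarray(b).tolist() for b in self.b_matrices],
            "direct_local": self.direct_local.to_dict(),
            "direct_regional": self.direct_regional.to_dict(),
            "psd_flag": bool(self.psd_flag),
        }


def _wls_structure_sills(
    emp: EmpiricalVariogram,
    structures: Sequence[Structure],
    nonneg: bool,
) -> np.ndarray:
    """WLS coefficients of the structure variogram parts for one empirical curve."""
    h = emp.bin_centers
    g = emp.gamma
    w = np.sqrt(emp.counts.astype(float)) / h
    A = np.column_stack([s.variogram_part(h) for s in structures])
    Aw = A * w[:, None]
    gw = g * w
    if nonneg:
        coef, _ = nnls(Aw, gw)
    else:
        coef, *_ = np.linalg.lstsq(Aw, gw, rcond=None)
    return coef


def fit_lmc(
    residuals: ResidualSet,
    coords,
    family: str = "spherical",
    lag_size: float | None = None,
    n_lags: int = 12,
) -> CoregionalizationModel:
    """Fit a two-variable LMC to the spatial and regional residuals.

    Procedure: (1) fit single-structure variograms marginally to each
    residual series — their ranges define the shared local and regional
    structures; (2) refit the sills of [nugget, local, regional] for both
    direct variograms (nonnegative WLS) and the cross-variogram (signed
    WLS); (3) clip each cross coefficient to |b_sr| <= sqrt(b_ss * b_rr) so
    every structure's 2x2 matrix is positive semidefinite, recording whether
    clipping occurred in ``psd_flag``.
    """
    coords = np.asarray(coords, dtype=float)
    if lag_size is None:
        lag_size = mean_nn_distance(coords)

    emp_s = empirical_variogram(residuals.spatial, coords, lag_size, n_lags)
    emp_r = empirical_variogram(residuals.regional, coords, lag_size, n_lags)
    emp_x = empirical_cross_variogram(
        residuals.spatial, residuals.regional, coords, lag_size, n_lags
    )
    direct_local = fit_variogram(emp_s, family)
    direct_regional = fit_variogram(emp_r, family)

    structures = [Structure("nugget")]
    r_loc, r_reg = direct_local.range_m, direct_regional.range_m
    structures.append(Structure(family, range_m=r_loc, exponent=direct_local.stable_exponent))
    # collapse to one correlated structure when the two ranges are indistinct
    if abs(r_reg - r_loc) > 0.05 * max(r_reg, r_loc):
        structures.append(
            Structure(family, range_m=r_reg, exponent=direct_regional.stable_exponent)
        )

    sill_ss = _wls_structure_sills(emp_s, structures, nonneg=True)
    sill_rr = _wls_structure_sills(emp_r, structures, nonneg=True)
    sill_sr = _wls_structure_sills(emp_x, structures, nonneg=False)

    psd_flag = False
    b_matrices = []
    for k in range(len(structures)):
        bound = np.sqrt(sill_ss[k] * sill_rr[k])
        cross = sill_sr[k]
        if abs(cross) > bound:
            cross = np.sign(cross) * bound
            psd_flag = True
        b_matrices.append(
            np.array([[sill_ss[k], cross], [cross, sill_rr[k]]], dtype=float)
        )
    return CoregionalizationModel(
        structures=structures,
        b_matrices=b_matrices,
        direct_local=direct_local,
        direct_regional=direct_regional,
        psd_flag=psd_flag,
    )


# ----------------------------------------------------------------- cokriging
@dataclass
class CokrigeResult:
    """Cokriging output at one or more targets."""

    estimate: np.ndarray
    variance: np.ndarray
    weights: list[tuple[np.ndarray, np.ndarray]]  # (lambda_s, lambda_r) per target
    neighborhoods: list[np.ndarray]  # neighbour indices per target


def _solve_with_jitter(K: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return np.linalg.solve(K + jitter * np.eye(len(K)), rhs)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("cokriging system singular even after jitter")


def cokrige(
    targets,
    residuals: ResidualSet,
    coords,
    model: CoregionalizationModel,
    n_neighbors: int = 16,
    max_radius: float | None = None,
    mode: str = "simple",
    exclude_self: bool = False,
) -> CokrigeResult:
    """Cokrige the spatial residual at target points.

    The predictor is  eps_hat(t) = sum_j w_s[j] eps_s(j) + sum_j w_r[j] eps_r(j)
    over the ``n_neighbors`` nearest sites within ``max_radius`` (default:
    the regional — longest — structure range).  ``mode='simple'`` assumes
    known zero means (both residual series are mean-zero by construction);
    ``mode='ordinary'`` enforces sum(w_s)=1, sum(w_r)=0.
    ``exclude_self`` drops neighbours at zero distance (used by LOOCV).
    """
    if mode not in ("simple", "ordinary"):
        raise ValueError("mode must be 'simple' or 'ordinary'")
    coords = np.asarray(coords, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if max_radius is None:
        ranges = [s.range_m for s in model.structures if s.family != "nugget"]
        max_radius = max(ranges) if ranges else np.inf
    tree = cKDTree(coords)
    k = min(n_neighbors + (1 if exclude_self else 0), len(coords))
    dist, idx = tree.query(targets, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)

    estimates = np.zeros(len(targets))
    variances = np.zeros(len(targets))
    weights: list[tuple[np.ndarray, np.ndarray]] = []
    hoods: list[np.ndarray] = []
    c0 = float(model.covariance(np.array([0.0]), 0, 0)[0])

    for t in range(len(targets)):
        sel = np.isfinite(dist[t])
        if exclude_self:
            sel &= dist[t] > 1e-9
        sel &= dist[t] <= max_radius
        nb = idx[t][sel]
        if len(nb) == 0:
            # fall back to the single nearest admissible site
            order = np.argsort(dist[t])
            nb = idx[t][order[1 if exclude_self else 0 :][:1]]
        hoods.append(nb)
        m = len(nb)
        pc = coords[nb]
        dd = np.hypot(pc[:, 0, None] - pc[None, :, 0], pc[:, 1, None] - pc[None, :, 1])
        d0 = np.hypot(pc[:, 0] - targets[t, 0], pc[:, 1] - targets[t, 1])

        K = np.empty((2 * m, 2 * m))
        K[:m, :m] = model.covariance(dd, 0, 0)
        K[:m, m:] = model.covariance(dd, 0, 1)
        K[m:, :m] = K[:m, m:].T
        K[m:, m:] = model.covariance(dd, 1, 1)
        k_vec = np.concatenate([model.covariance(d0, 0, 0), model.covariance(d0, 1, 0)])

        if mode == "simple":
            w = _solve_with_jitter(K, k_vec)
            ws, wr = w[:m], w[m:]
            var = c0 - w @ k_vec
        else:
            A = np.zeros((2 * m + 2, 2 * m + 2))
            A[: 2 * m, : 2 * m] = K
            A[:m, 2 * m] = 1.0
            A[m:2 * m, 2 * m + 1] = 1.0
            A[2 * m, :m] = 1.0
            A[2 * m + 1, m:2 * m] = 1.0
            rhs = np.concatenate([k_vec, [1.0, 0.0]])
            sol = _solve_with_jitter(A, rhs)
            ws, wr = sol[:m], sol[m:2 * m]
            var = c0 - sol[: 2 * m] @ k_vec - sol[2 * m] - 0.0 * sol[2 * m + 1]
        estimates[t] = ws @ residuals.spatial[nb] + wr @ residuals.regional[nb]
        variances[t] = max(float(var), 0.0)
        weights.append((ws, wr))
    return CokrigeResult(
        estimate=estimates, variance=variances, weights=weights, neighborhoods=hoods
    )


def ordinary_kriging(
    targets,
    values,
    coords,
    model: VariogramModel,
    n_neighbors: int = 16,
    max_radius: float | None = None,
    exclude_self: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-variable ordinary kriging (unit-sum weights); returns (estimate, variance)."""
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if max_radius is None:
        max_radius = np.inf
    tree = cKDTree(coords)
    k = min(n_neighbors + (1 if exclude_self else 0), len(coords))
    dist, idx = tree.query(targets, k=k)
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    est = np.zeros(len(targets))
    var = np.zeros(len(targets))
    for t in range(len(targets)):
        sel = np.isfinite(dist[t])
        if exclude_self:
            sel &= dist[t] > 1e-9
        within = sel & (dist[t] <= max_radius)
        nb = idx[t][within] if within.any() else idx[t][sel][:1]
        m = len(nb)
        pc = coords[nb]
        dd = np.hypot(pc[:, 0, None] - pc[None, :, 0], pc[:, 1, None] - pc[None, :, 1])
        d0 = np.hypot(pc[:, 0] - targets[t, 0], pc[:, 1] - targets[t, 1])
        A = np.zeros((m + 1, m + 1))
        A[:m, :m] = model.covariance(dd)
        A[:m, m] = 1.0
        A[m, :m] = 1.0
        rhs = np.concatenate([model.covariance(d0), [1.0]])
        sol = _solve_with_jitter(A, rhs)
        est[t] = sol[:m] @ values[nb]
        var[t] = max(float(model.covariance(np.array([0.0]))[0] - sol[:m] @ rhs[:m] - sol[m]), 0.0)
    return est, var


class ResidualCokriger(BaseEstimator):
    """Estimator wrapper: fit an LMC to residual pairs, predict eps_s anywhere.

    ``fit(X, y)`` takes ``X`` = (n, 2) coordinates and ``y`` = (n, 2) array
    whose columns are the spatial and regional residuals.
    """

    def __init__(
        self,
        family: str = "spherical",
        lag_size: float | None = None,
        n_lags: int = 12,
        n_neighbors: int = 16,
        max_radius: float | None = None,
        mode: str = "simple",
        lmc: CoregionalizationModel | None = None,
    ):
        self.family = family
        self.lag_size = lag_size
        self.n_lags = n_lags
        self.n_neighbors = n_neighbors
        self.max_radius = max_radius
        self.mode = mode
        self.lmc = lmc  # pre-fitted structure; skips per-fit variogram estimation

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): spatial and regional residual columns")
        self.coords_ = X
        self.residuals_ = ResidualSet(spatial=y[:, 0], regional=y[:, 1])
        if self.lmc is not None:
            self.lmc_ = self.lmc
        else:
            self.lmc_ = fit_lmc(
                self.residuals_, X, family=self.family, lag_size=self.lag_size, n_lags=self.n_lags
            )
        return self

    def predict(self, X, return_variance: bool = False, exclude_self: bool = False):
        res = cokrige(
            np.asarray(X, dtype=float),
            self.residuals_,
            self.coords_,
            self.lmc_,
            n_neighbors=self.n_neighbors,
            max_radius=self.max_radius,
            mode=self.mode,
            exclude_self=exclude_self,
        )
        if return_variance:
            return res.estimate, res.variance
        return res.estimate
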