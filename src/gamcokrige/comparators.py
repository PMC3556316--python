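"""Comparator models for the four-way evaluation.

* :class:`PoissonGLM` — Poisson log-link regression with every covariate
  entering linearly (no smooths, no spatial term beyond linear coordinates
  if listed).
* :class:`UniversalKriging` — a polynomial-in-coordinates trend for the
  counts plus ordinary kriging of the trend residuals; it uses no thematic
  covariates at all.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .kriging import ordinary_kriging
from .variograms import empirical_variogram, fit_variogram, mean_nn_distance

__all__ = ["PoissonGLM", "UniversalKriging"]


class PoissonGLM(BaseEstimator, RegressorMixin):
    """All-linear Poisson log-link regression on the named covariate columns."""

    def __init__(self, terms=None, coord_cols: tuple[str, str] = ("x", "y"), include_coords: bool = True):
        self.terms = terms
        self.coord_cols = coord_cols
        self.include_coords = include_coords

    def _design(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        for t in self.terms_:
            cols.append(X[t].to_numpy(dtype=float))
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        terms = [str(t) for t in (self.terms or [])]
        if self.include_coords:
            terms += [c for c in self.coord_cols if c not in terms]
        self.terms_ = terms
        self.results_ = sm.GLM(y, self._design(X), family=sm.families.Poisson()).fit(maxiter=200)
        self.coef_ = np.asarray(self.results_.params)
        self.fitted_means_ = np.asarray(self.results_.fittedvalues)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "results_")
        return np.exp(self._design(pd.DataFrame(X)) @ self.coef_)


class UniversalKriging(BaseEstimator, RegressorMixin):
    """Coordinate-trend regression plus ordinary kriging of the residual counts.

    The trend is an ordinary least-squares polynomial in (x, y) of
    ``trend_order`` (1 = planar, 2 = quadratic).  The residual variogram is
    fitted by WLS and residuals are kriged with unit-sum weights.
    """

    def __init__(
        self,
        trend_order: int = 1,
        family: str = "spherical",
        n_neighbors: int = 16,
        max_radius: float | None = None,
        lag_size: float | None = None,
        n_lags: int = 12,
        coord_cols: tuple[str, str] = ("x", "y"),
    ):
        self.trend_order = trend_order
        self.family = family
        self.n_neighbors = n_neighbors
        self.max_radius = max_radius
        self.lag_size = lag_size
        self.n_lags = n_lags
        self.coord_cols = coord_cols

    def _trend_design(self, coords: np.ndarray) -> np.ndarray:
        # scale to km so polynomial columns are well conditioned
        x, y = coords[:, 0] / 1e3, coords[:, 1] / 1e3
        cols = [np.ones(len(coords)), x, y]
        if self.trend_order >= 2:
            cols += [x * y, x**2, y**2]
        return np.column_stack(cols)

    def fit(self, X: pd.DataFrame, y):
        if self.trend_order not in (1, 2):
            raise ValueError("trend_order must be 1 or 2")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        coords = X[list(self.coord_cols)].to_numpy(dtype=float)
        design = self._trend_design(coords)
        self.beta_, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ self.beta_
        emp = empirical_variogram(resid, coords, lag_size=self.lag_size, n_lags=self.n_lags)
        self.variogram_ = fit_variogram(emp, self.family)
        self.coords_ = coords
        self.resid_ = resid
        return self

    def predict(self, X: pd.DataFrame, exclude_self: bool = False) -> np.ndarray:
        check_is_fitted(self, "beta_")
        X = pd.DataFrame(X)
        coords = X[list(self.coord_cols)].to_numpy(dtype=float)
        trend = self._trend_design(coords) @ self.beta_
        eps, _ = ordinary_kriging(
            coords,
            self.resid_,
            self.coords_,
            self.variogram_,
            n_neighbors=self.n_neighbors,
            max_radius=self.max_radius,
            exclude_self=exclude_self,
        )
        return trend + eps
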