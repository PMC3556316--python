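"""The headline two-stage model: additive Poisson means plus cokriged residuals.

Stage 1 fits the Poisson GAM to the observed counts, giving local means
mu_hat.  Stage 2 forms the spatial residual (count - mu_hat) and the
regional residual (count - overall mean), fits a linear model of
coregionalization to the pair, and cokriges the spatial residual at
prediction targets.  The combined expected count is

    lambda_hat = max(mu_hat + eps_hat, lambda_floor)

on the count (response) scale, floored at a small positive value because the
additive combination can fall below zero while an expected count cannot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .gam import PoissonGAM
from .kriging import ResidualCokriger, compute_residuals

__all__ = ["GamCokriging", "fit_combined", "predict_combined"]


class GamCokriging(BaseEstimator, RegressorMixin):
    """Poisson GAM for local means + simple cokriging of its residuals.

    ``X`` must be a DataFrame containing the coordinate columns
    (``coord_cols``) and every covariate named in the term lists; ``y`` are
    the observed counts.  ``predict`` returns floored expected counts.

    Attributes (after fit): ``gam_``, ``residuals_``, ``cokriger_`` (with its
    fitted ``lmc_``), ``fitted_lambda_`` (in-sample combined expectation).
    """

    def __init__(
        self,
        smooth_terms=None,
        linear_terms=None,
        df: int = 6,
        coord_term: bool = True,
        coord_df: int = 3,
        coord_cols: tuple[str, str] = ("x", "y"),
        family: str = "spherical",
        lag_size: float | None = None,
        n_lags: int = 20,
        n_neighbors: int = 24,
        max_radius: float | None = None,
        mode: str = "simple",
        lambda_floor: float = 1e-3,
        fixed_lmc=None,
    ):
        self.smooth_terms = smooth_terms
        self.linear_terms = linear_terms
        self.df = df
        self.coord_term = coord_term
        self.coord_df = coord_df
        self.coord_cols = coord_cols
        self.family = family
        self.lag_size = lag_size
        self.n_lags = n_lags
        self.n_neighbors = n_neighbors
        self.max_radius = max_radius
        self.mode = mode
        self.lambda_floor = lambda_floor
        self.fixed_lmc = fixed_lmc  # reuse a full-data LMC instead of refitting

    def fit(self, X: pd.DataFrame, y):
        if self.lambda_floor <= 0:
            raise ValueError("lambda_floor must be positive")
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) < 2:
            raise ValueError("insufficient data: need at least two sites")
        self.gam_ = PoissonGAM(
            smooth_terms=self.smooth_terms,
            linear_terms=self.linear_terms,
            df=self.df,
            coord_term=self.coord_term,
            coord_df=self.coord_df,
            coord_cols=self.coord_cols,
        ).fit(X, y)
        self.residuals_ = compute_residuals(y, self.gam_.fitted_means_)
        coords = X[list(self.coord_cols)].to_numpy(dtype=float)
        self.cokriger_ = ResidualCokriger(
            family=self.family,
            lag_size=self.lag_size,
            n_lags=self.n_lags,
            n_neighbors=self.n_neighbors,
            max_radius=self.max_radius,
            mode=self.mode,
            lmc=self.fixed_lmc,
        ).fit(coords, np.column_stack([self.residuals_.spatial, self.residuals_.regional]))
        self.lmc_ = self.cokriger_.lmc_
        self.train_coords_ = coords
        return self

    @property
    def fitted_lambda_(self) -> np.ndarray:
        """In-sample combined expectation (computed lazily: n cokriging solves)."""
        check_is_fitted(self, "gam_")
        if not hasattr(self, "_fitted_lambda"):
            eps_in = self.cokriger_.predict(self.train_coords_)
            self._fitted_lambda = np.maximum(
                self.gam_.fitted_means_ + eps_in, self.lambda_floor
            )
        return self._fitted_lambda

    def predict(self, X: pd.DataFrame, exclude_self: bool = False) -> np.ndarray:
        """lambda_hat = max(mu_hat + eps_hat, lambda_floor); strictly positive."""
        check_is_fitted(self, "gam_")
        X = pd.DataFrame(X)
        mu = self.gam_.predict(X)
        coords = X[list(self.coord_cols)].to_numpy(dtype=float)
        eps = self.cokriger_.predict(coords, exclude_self=exclude_self)
        return np.maximum(mu + eps, self.lambda_floor)


def fit_combined(sites: pd.DataFrame, **params) -> GamCokriging:
    """Fit the combined model to a site table with a ``count`` column."""
    return GamCokriging(**params).fit(sites, sites["count"].to_numpy())


def predict_combined(fit: GamCokriging, targets: pd.DataFrame) -> np.ndarray:
    return fit.predict(targets)
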