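"""Leave-one-out cross-validation, error metrics, model comparison, sensitivity.

Prediction error is observed minus predicted.  Summary metrics per model:

* R² — squared Pearson correlation of observed and predicted values
  (undefined, reported as NaN, when either vector has zero variance);
* median error and IQR of the error distribution;
* RMSPE — root mean squared prediction error;
* Tukey box-plot statistics (quartiles, 1.5×IQR whiskers, outliers).

The four-model comparison (Poisson GLM, universal kriging, GAM, GAM plus
cokriging) always evaluates every model on the identical leave-one-out
folds, so differences are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .comparators import PoissonGLM, UniversalKriging
from .gam import PoissonGAM
from .pipeline import GamCokriging
from .variograms import FAMILIES

__all__ = [
    "BoxplotStats",
    "CvReport",
    "error_metrics",
    "loocv",
    "compare_models",
    "comparison_table",
    "sensitivity_analysis",
]


@dataclass
class BoxplotStats:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def _boxplot_stats(errors: np.ndarray) -> BoxplotStats:
    q1, med, q3 = np.percentile(errors, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = errors[(errors >= lo_fence) & (errors <= hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()) if len(inside) else float(q1),
        whisker_high=float(inside.max()) if len(inside) else float(q3),
        outliers=errors[(errors < lo_fence) | (errors > hi_fence)],
    )


def _zero_variance(v: np.ndarray) -> bool:
    return float(np.std(v)) <= 1e-12 * (abs(float(np.mean(v))) + 1.0)


def error_metrics(observed, predicted) -> dict:
    """R², median error, IQR and RMSPE of (observed - predicted)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or len(observed) < 3:
        raise ValueError("observed and predicted must be equal-length vectors, n >= 3")
    errors = observed - predicted
    if _zero_variance(observed) or _zero_variance(predicted):
        r2 = np.nan
    else:
        r2 = float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    q1, q3 = np.percentile(errors, [25, 75])
    return {
        "r2": r2,
        "median_error": float(np.median(errors)),
        "iqr": float(q3 - q1),
        "rmspe": float(np.sqrt(np.mean(errors**2))),
    }


@dataclass
class CvReport:
    """Per-model LOOCV output."""

    model_name: str
    observed: np.ndarray
    predicted: np.ndarray
    fold_indices: np.ndarray
    failed_folds: list[int] = field(default_factory=list)

    @property
    def errors(self) -> np.ndarray:
        return self.observed - self.predicted

    @property
    def complete(self) -> bool:
        return not self.failed_folds

    def metrics(self) -> dict:
        ok = np.isfinite(self.predicted)
        return error_metrics(self.observed[ok], self.predicted[ok])

    @property
    def r2(self) -> float:
        return self.metrics()["r2"]

    def boxplot_stats(self) -> BoxplotStats:
        ok = np.isfinite(self.predicted)
        return _boxplot_stats(self.errors[ok])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fold": self.fold_indices,
                "observed": self.observed,
                "predicted": self.predicted,
                "error": self.errors,
            }
        )


def loocv(estimator, X: pd.DataFrame, y, model_name: str | None = None) -> CvReport:
    """Leave-one-out CV: refit a clone on n-1 sites, predict the held-out one.

    A fold whose fit or prediction raises is recorded as failed (NaN
    prediction) rather than aborting the whole report.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    n = len(X)
    if n < 10:
        raise ValueError("LOOCV requires at least 10 sites")
    predicted = np.full(n, np.nan)
    failed: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            est = clone(estimator)
            est.fit(X[mask], y[mask])
            predicted[i] = float(np.asarray(est.predict(X[~mask]))[0])
        except Exception:  # noqa: BLE001 - fold-level robustness by design
            failed.append(i)
    return CvReport(
        model_name=model_name or type(estimator).__name__,
        observed=y,
        predicted=predicted,
        fold_indices=np.arange(n),
        failed_folds=failed,
    )


def _comparison_models(
    smooth_terms,
    linear_terms,
    df: int,
    coord_df: int,
    family: str,
    n_neighbors: int,
    max_radius,
    mode: str,
    lambda_floor: float,
    coord_cols,
    n_lags: int,
) -> dict:
    smooth_names = [t[0] if isinstance(t, (tuple, list)) else t for t in (smooth_terms or [])]
    all_terms = list(smooth_names) + list(linear_terms or [])
    return {
        "glm": PoissonGLM(terms=all_terms, coord_cols=coord_cols, include_coords=True),
        "universal_kriging": UniversalKriging(
            family=family, n_neighbors=n_neighbors, coord_cols=coord_cols
        ),
        "gam": PoissonGAM(
            smooth_terms=smooth_terms,
            linear_terms=linear_terms,
            df=df,
            coord_term=True,
            coord_df=coord_df,
            coord_cols=coord_cols,
        ),
        "combined": GamCokriging(
            smooth_terms=smooth_terms,
            linear_terms=linear_terms,
            df=df,
            coord_df=coord_df,
            coord_cols=coord_cols,
            family=family,
            n_neighbors=n_neighbors,
            max_radius=max_radius,
            mode=mode,
            lambda_floor=lambda_floor,
            n_lags=n_lags,
        ),
    }


def compare_models(
    X: pd.DataFrame,
    y,
    smooth_terms=None,
    linear_terms=None,
    df: int = 6,
    coord_df: int = 3,
    family: str = "spherical",
    n_neighbors: int = 24,
    max_radius=None,
    mode: str = "simple",
    lambda_floor: float = 1e-3,
    coord_cols: tuple[str, str] = ("x", "y"),
    n_lags: int = 20,
    refit_variogram_per_fold: bool = True,
) -> dict[str, CvReport]:
    """LOOCV reports for GLM, universal kriging, GAM and the combined model.

    All four models see identical folds.  With
    ``refit_variogram_per_fold=False`` the residual (co)variogram structure
    is fitted once on the full data and held fixed across folds — the common
    GIS shortcut — while the regression stages are still refit per fold.
    """
    X = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=float)
    models = _comparison_models(
        smooth_terms, linear_terms, df, coord_df, family, n_neighbors,
        max_radius, mode, lambda_floor, coord_cols, n_lags,
    )
    if not refit_variogram_per_fold:
        full_combined = clone(models["combined"]).fit(X, y)
        models["combined"].set_params(fixed_lmc=full_combined.lmc_)
    reports = {name: loocv(m, X, y, model_name=name) for name, m in models.items()}
    folds = [r.fold_indices for r in reports.values()]
    assert all(np.array_equal(folds[0], f) for f in folds)
    return reports


def comparison_table(reports: dict[str, CvReport]) -> pd.DataFrame:
    """Summary table: one row per model with cv_r2, median error, IQR, RMSPE."""
    rows = []
    for name, rep in reports.items():
        m = rep.metrics()
        rows.append(
            {
                "model": name,
                "cv_r2": m["r2"],
                "median_error": m["median_error"],
                "iqr": m["iqr"],
                "rmspe": m["rmspe"],
                "failed_folds": len(rep.failed_folds),
            }
        )
    return pd.DataFrame(rows)


def sensitivity_analysis(
    X: pd.DataFrame,
    y,
    df_values=range(5, 11),
    families=FAMILIES,
    smooth_terms=None,
    linear_terms=None,
    **model_params,
) -> tuple[pd.DataFrame, dict]:
    """LOOCV R² of the combined model across smooth df and variogram family.

    Returns the grid as a DataFrame (columns df, family, r2 — NaN for
    combinations that failed) and a summary dict (median, mean, 2.5/97.5
    percentiles over the successful values).
    """
    rows = []
    for df in df_values:
        for family in families:
            model = GamCokriging(
                smooth_terms=smooth_terms,
                linear_terms=linear_terms,
                df=int(df),
                family=family,
                **model_params,
            )
            try:
                rep = loocv(model, X, y, model_name=f"df={df},{family}")
                r2 = rep.metrics()["r2"]
            except Exception:  # noqa: BLE001 - failed combinations recorded, not fatal
                r2 = np.nan
            rows.append({"df": int(df), "family": family, "r2": r2})
    grid = pd.DataFrame(rows)
    vals = grid["r2"].dropna().to_numpy()
    summary = {
        "median": float(np.median(vals)) if len(vals) else np.nan,
        "mean": float(np.mean(vals)) if len(vals) else np.nan,
        "ci95": (
            [float(v) for v in np.percentile(vals, [2.5, 97.5])] if len(vals) else [np.nan, np.nan]
        ),
        "n_failed": int(grid["r2"].isna().sum()),
    }
    return grid, summary
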