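"""Three-step covariate selection for the additive count model.

1. **VIF partition** — covariates with variance inflation factor below a
   threshold (default 5) are "weak" and always enter together; the remaining
   highly collinear covariates are split into groups by connected components
   of the |correlation| >= corr_threshold graph.
2. **Combination enumeration** — every combination taking exactly one member
   from each collinear group, joined with all weak covariates.
3. **Backward elimination** — each combination is fitted as a Poisson
   additive model and the least significant term (largest p >= alpha,
   default 0.1) is dropped one at a time until every remaining term is
   significant; the combination whose final model has the highest R² wins
   (ties: fewer covariates, then lexicographic).

R² is the squared Pearson correlation between observed counts and fitted
means by default; deviance explained is available behind ``criterion``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .gam import PoissonGAM

__all__ = [
    "compute_vif",
    "group_covariates",
    "SelectionResult",
    "CovariateSelector",
    "select_covariates",
]


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1/(1 - R²_j) from regressing covariate j on all the others.

    Exact collinearity yields ``inf`` rather than an exception.
    """
    X = pd.DataFrame(X)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more rows than covariates + 1 to compute VIFs")
    arr = X.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        others = np.delete(arr, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ beta
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else max(1.0 / (1.0 - r2), 1.0)
    return pd.Series(out, name="vif")


def group_covariates(
    X: pd.DataFrame,
    vif_threshold: float = 5.0,
    corr_threshold: float = 0.7,
) -> tuple[list[str], list[list[str]]]:
    """Split covariates into the weak (VIF < threshold) set and collinear groups.

    Strong covariates are partitioned into connected components of the graph
    whose edges join pairs with |Pearson r| >= ``corr_threshold``.
    """
    X = pd.DataFrame(X)
    vif = compute_vif(X)
    weak = [c for c in X.columns if vif[c] < vif_threshold]
    strong = [c for c in X.columns if c not in weak]
    if not strong:
        return weak, []
    sub = X[strong].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr))
    adj = (np.abs(corr) >= corr_threshold).astype(int)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[strong[i] for i in range(len(strong)) if labels[i] == k] for k in range(n_comp)]
    return weak, [sorted(g) for g in sorted(groups, key=lambda g: sorted(g)[0])]


@dataclass
class SelectionResult:
    vif_table: pd.Series
    weak: list[str]
    groups: list[list[str]]
    combinations_tried: int
    selected: list[str]
    final_r2: float
    per_covariate_stats: pd.DataFrame
    model: PoissonGAM | None = None


class CovariateSelector(BaseEstimator):
    """Estimator running the three-step selection on candidate columns of X.

    Parameters
    ----------
    candidates : list of str, optional
        Candidate covariate columns (default: every column of ``X`` except
        the coordinate columns).
    smooth_candidates : list of str or {name: df}, optional
        Candidates entering through a smooth instead of linearly.
    alpha : float
        Per-term significance threshold for backward elimination.
    criterion : "pearson" | "deviance"
        Model score used to rank combinations.
    include_coords : bool
        Force a bivariate coordinate smooth into every model (never subject
        to elimination).
    """

    def __init__(
        self,
        candidates=None,
        smooth_candidates=None,
        df: int = 4,
        alpha: float = 0.1,
        vif_threshold: float = 5.0,
        corr_threshold: float = 0.7,
        criterion: str = "pearson",
        include_coords: bool = False,
        coord_df: int = 3,
        coord_cols: tuple[str, str] = ("x", "y"),
    ):
        self.candidates = candidates
        self.smooth_candidates = smooth_candidates
        self.df = df
        self.alpha = alpha
        self.vif_threshold = vif_threshold
        self.corr_threshold = corr_threshold
        self.criterion = criterion
        self.include_coords = include_coords
        self.coord_df = coord_df
        self.coord_cols = coord_cols

    # ------------------------------------------------------------------ helpers
    def _smooth_df(self, name: str) -> int | None:
        sc = self.smooth_candidates
        if sc is None:
            return None
        if isinstance(sc, dict):
            return int(sc[name]) if name in sc else None
        return self.df if name in sc else None

    def _make_gam(self, terms: list[str]) -> PoissonGAM:
        smooth = []
        linear = []
        for t in terms:
            d = self._smooth_df(t)
            (smooth.append((t, d)) if d is not None else linear.append(t))
        return PoissonGAM(
            smooth_terms=smooth,
            linear_terms=linear,
            df=self.df,
            coord_term=self.include_coords,
            coord_df=self.coord_df,
            coord_cols=self.coord_cols,
        )

    def _score(self, model: PoissonGAM) -> float:
        if self.criterion == "deviance":
            val = model.deviance_explained_
        else:
            val = model.r2_
        return 0.0 if not np.isfinite(val) else float(val)

    def _removable_pvalues(self, model: PoissonGAM, terms: list[str]) -> pd.Series:
        stats = model.term_stats_
        return stats.loc[[t for t in terms if t in stats.index], "p_value"]

    def _backward(self, X: pd.DataFrame, y: np.ndarray, terms: list[str]):
        """Drop the worst-p term (p >= alpha) one at a time; return final model."""
        terms = list(terms)
        while True:
            model = self._make_gam(terms).fit(X, y)
            if not terms:
                return model, terms
            pvals = self._removable_pvalues(model, terms).dropna()
            if pvals.empty:
                return model, terms
            worst = pvals.idxmax()
            if pvals[worst] < self.alpha:
                return model, terms
            terms.remove(worst)

    # ----------------------------------------------------------------------- fit
    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        cands = list(self.candidates) if self.candidates is not None else [
            c for c in X.columns if c not in self.coord_cols
        ]
        if not cands:
            raise ValueError("no candidate covariates")
        vif = compute_vif(X[cands])
        weak, groups = group_covariates(
            X[cands], vif_threshold=self.vif_threshold, corr_threshold=self.corr_threshold
        )

        best = None
        tried = 0
        pools = [sorted(g) for g in groups] or [[]]
        for picks in itertools.product(*pools) if groups else [()]:
            terms = sorted(weak) + [p for p in picks if p]
            tried += 1
            try:
                model, kept = self._backward(X, y, terms)
            except (RuntimeError, ValueError):
                continue
            key = (-self._score(model), len(kept), tuple(sorted(kept)))
            if best is None or key < best[0]:
                best = (key, model, kept)
        if best is None:
            raise RuntimeError(
                "covariate selection failed: no combination produced a fittable model"
            )
        _, model, kept = best
        self.model_ = model
        self.selected_ = sorted(kept)
        self.vif_ = vif
        self.weak_ = weak
        self.groups_ = groups
        self.combinations_tried_ = tried
        self.final_r2_ = self._score(model)
        self.per_covariate_stats_ = self._stats_table(X, y, model, self.selected_)
        self.result_ = SelectionResult(
            vif_table=vif,
            weak=weak,
            groups=groups,
            combinations_tried=tried,
            selected=self.selected_,
            final_r2=self.final_r2_,
            per_covariate_stats=self.per_covariate_stats_,
            model=model,
        )
        return self

    def _stats_table(
        self, X: pd.DataFrame, y: np.ndarray, model: PoissonGAM, selected: list[str]
    ) -> pd.DataFrame:
        """Per-selected-covariate marginal R, variance proportion, F-like stat, p.

        V.P is the drop in model R² (in percent) when the term is removed
        from the final model, a leave-one-term-out share of explained
        variance.
        """
        rows = []
        full_score = self._score(model)
        for name in selected:
            xv = X[name].to_numpy(dtype=float)
            r = float(np.corrcoef(xv, y)[0, 1]) if np.std(xv) > 0 and np.std(y) > 0 else np.nan
            try:
                reduced = self._make_gam([t for t in selected if t != name]).fit(X, y)
                vp = 100.0 * max(full_score - self._score(reduced), 0.0)
            except (RuntimeError, ValueError):
                vp = np.nan
            ts = model.term_stats_
            chi2 = ts.loc[name, "chi2"] if name in ts.index else np.nan
            dfk = ts.loc[name, "df"] if name in ts.index else np.nan
            p = ts.loc[name, "p_value"] if name in ts.index else np.nan
            rows.append(
                {"covariate": name, "R": r, "VP_percent": vp, "F": chi2 / dfk if dfk else np.nan, "p_value": p}
            )
        return pd.DataFrame(rows)


def select_covariates(sites: pd.DataFrame, candidates=None, **selector_params) -> SelectionResult:
    """Functional wrapper: run the selector on a site table with a ``count`` column."""
    sel = CovariateSelector(candidates=candidates, **selector_params)
    sel.fit(sites, sites["count"].to_numpy())
    return sel.result_
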