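"""Leave-one-out evaluation and F-threshold selection.

With only 20 training rows and 13 candidate predictors, in-sample fit
statistics are optimistic; prediction quality is therefore measured by
leave-one-out cross-validation.  For a candidate F threshold, each amino
acid in turn is held out, a stepwise model is selected and fitted on the
remaining rows, and the held-out value is predicted (falling back to the
training mean when no predictor survives the gate).  The Pearson correlation
between held-out predictions and true values, r_jn, scores the threshold;
the grid value maximizing r_jn wins, with ties resolved toward the largest
threshold (fewest predictors).  The reported RMSE is computed from the same
leave-one-out prediction vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .stepwise import StepwiseError, stepwise_select, ols_fit

__all__ = [
    "TrainedModel",
    "pearson",
    "rmse",
    "loo_predict",
    "threshold_grid",
    "optimize_threshold",
    "ThresholdSearchRegressor",
]

DEFAULT_GRID = (0.5, 12.0, 0.1)


@dataclass
class TrainedModel:
    """Final per-property model plus its quality statistics.

    ``b`` maps selected component keys to coefficients; ``f_star`` is the
    chosen F threshold (NaN for degenerate perfect-correlation properties,
    where the statistic is undefined); ``r_jn`` and ``rmse`` are computed
    from leave-one-out predictions at ``f_star``.
    """

    accession: str
    selected: tuple[str, ...]
    b: dict[str, float]
    constant: float
    f_star: float
    r_jn: float
    r_insample: float
    p_num: int
    rmse: float
    n_used: int
    description: str = ""
    perfect_fit: bool = False
    rmse_basis: str = "loo"
    na_dropped: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selected"] = list(self.selected)
        d["na_dropped"] = list(self.na_dropped)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        d = dict(d)
        d["selected"] = tuple(d.get("selected", ()))
        d["na_dropped"] = tuple(d.get("na_dropped", ()))
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        return cls(**{k: v for k, v in d.items() if k in known})


def pearson(a, b) -> float:
    """Sample Pearson correlation; errors on constant input or length < 3."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b):
        raise ValueError("inputs have different lengths")
    if len(a) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def rmse(pred, actual) -> float:
    """Root mean square error between two equal-length vectors."""
    pred = np.asarray(pred, dtype=float).ravel()
    actual = np.asarray(actual, dtype=float).ravel()
    if len(pred) != len(actual):
        raise ValueError("inputs have different lengths")
    if len(pred) == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def loo_predict(X, y, f_threshold: float, columns: Sequence[str] | None = None) -> np.ndarray:
    """Held-out prediction for every row via leave-one-out stepwise fits.

    Row ``i`` is predicted by a model selected and fitted on the other
    ``n - 1`` rows at ``f_threshold``; zero-variance columns are dropped per
    fold.  Folds where no predictor survives predict the fold training mean.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns) if columns is None else list(columns)
        Xa = X[cols].to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        cols = list(columns) if columns is not None else [f"x{i}" for i in range(Xa.shape[1])]
    yv = np.asarray(y, dtype=float).ravel()
    n = len(yv)
    if n < 3:
        raise StepwiseError("leave-one-out needs at least 3 rows")
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        try:
            fit = stepwise_select(Xa[mask], yv[mask], f_threshold, columns=cols)
        except StepwiseError:
            preds[i] = float(np.mean(yv[mask]))
            continue
        pos = {c: j for j, c in enumerate(cols)}
        idx = [pos[k] for k in fit.selected]
        preds[i] = float(Xa[i, idx] @ fit.b + fit.constant)
    return preds


def threshold_grid(
    f_min: float = DEFAULT_GRID[0],
    f_max: float = DEFAULT_GRID[1],
    f_step: float = DEFAULT_GRID[2],
) -> np.ndarray:
    """Strictly increasing grid of F thresholds (inclusive of both ends)."""
    n = int(round((f_max - f_min) / f_step))
    grid = np.round(f_min + f_step * np.arange(n + 1), 9)
    return grid[grid <= f_max + 1e-9]


@dataclass
class _Scan:
    grid: np.ndarray
    r: list
    r_jn: list
    p_num: list

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f_threshold": self.grid, "r": self.r, "r_jn": self.r_jn, "p_num": self.p_num}
        )


def optimize_threshold(
    X,
    y,
    grid: Sequence[float] | None = None,
    accession: str = "",
    description: str = "",
    na_dropped: Sequence[str] = (),
) -> tuple[TrainedModel, pd.DataFrame]:
    """Scan a threshold grid, pick the best by LOO correlation, refit on all rows.

    Returns the trained model and the scan table (threshold, in-sample r,
    LOO r_jn, predictor count).  Ties in r_jn go to the largest threshold.
    For degenerate perfect-fit properties the threshold is meaningless and
    reported as NaN, with RMSE still taken from the LOO predictions.
    """
    grid_arr = threshold_grid() if grid is None else np.asarray(sorted(grid), dtype=float)
    if grid_arr.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid_arr) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    yv = np.asarray(y, dtype=float).ravel()

    scan = _Scan(grid_arr, [], [], [])
    best_t, best_r, best_preds = None, -np.inf, None
    loo_cache: dict[tuple, tuple] = {}
    for t in grid_arr:
        preds = loo_predict(X, yv, float(t))
        key = tuple(np.round(preds, 12))
        try:
            r_jn = loo_cache[key]
        except KeyError:
            try:
                r_jn = pearson(preds, yv)
            except ValueError:
                r_jn = math.nan
            loo_cache[key] = r_jn
        full = stepwise_select(X, yv, float(t))
        try:
            r_full = pearson(full.predict(_frame_or_array(X, full.selected)), yv)
        except ValueError:
            r_full = math.nan
        scan.r.append(r_full)
        scan.r_jn.append(r_jn)
        scan.p_num.append(full.p_num)
        if not math.isnan(r_jn) and r_jn >= best_r - 1e-12:
            best_t, best_r, best_preds = float(t), max(r_jn, best_r), preds

    if best_t is None:  # every threshold gave an undefined correlation
        best_t, best_preds = float(grid_arr[-1]), loo_predict(X, yv, float(grid_arr[-1]))
        best_r = math.nan

    final = stepwise_select(X, yv, best_t)
    try:
        r_insample = pearson(final.predict(_frame_or_array(X, final.selected)), yv)
    except ValueError:
        r_insample = math.nan
    model = TrainedModel(
        accession=accession,
        selected=final.selected,
        b=final.coef_dict(),
        constant=final.constant,
        f_star=math.nan if final.perfect_fit else best_t,
        r_jn=best_r,
        r_insample=r_insample,
        p_num=final.p_num,
        rmse=rmse(best_preds, yv),
        n_used=len(yv),
        description=description,
        perfect_fit=final.perfect_fit,
        na_dropped=tuple(na_dropped),
    )
    return model, scan.frame()


def _frame_or_array(X, selected):
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    pos = {f"x{i}": i for i in range(X.shape[1])}
    idx = [pos[k] for k in selected]
    return X[:, idx] if selected else X[:, :0]


class ThresholdSearchRegressor(RegressorMixin, BaseEstimator):
    """Stepwise regression with the F threshold chosen by leave-one-out CV.

    Parameters
    ----------
    f_min, f_max, f_step : float
        Threshold grid (default 0.5 to 12.0 in steps of 0.1).
    grid : sequence of float, optional
        Explicit grid overriding the min/max/step triple.

    Attributes
    ----------
    f_star_ : chosen threshold (NaN if the final fit is perfect)
    r_jn_ : leave-one-out Pearson correlation at ``f_star_``
    r_insample_ : full-fit Pearson correlation
    rmse_ : RMSE of the leave-one-out predictions at ``f_star_``
    p_num_ : number of selected predictors
    coef_, intercept_, selected_ : final full-data fit
    loo_predictions_ : held-out prediction per training row
    scan_ : DataFrame with one row per grid threshold
    model_ : the :class:`TrainedModel` summary
    """

    def __init__(self, f_min=DEFAULT_GRID[0], f_max=DEFAULT_GRID[1],
                 f_step=DEFAULT_GRID[2], grid=None, accession=""):
        self.f_min = f_min
        self.f_max = f_max
        self.f_step = f_step
        self.grid = grid
        self.accession = accession

    def fit(self, X, y):
        grid = (
            np.asarray(self.grid, dtype=float)
            if self.grid is not None
            else threshold_grid(self.f_min, self.f_max, self.f_step)
        )
        names = [str(c) for c in X.columns] if isinstance(X, pd.DataFrame) else None
        model, scan = optimize_threshold(X, y, grid=grid, accession=self.accession)
        self.model_ = model
        self.scan_ = scan
        self.f_star_ = model.f_star
        self.r_jn_ = model.r_jn
        self.r_insample_ = model.r_insample
        self.rmse_ = model.rmse
        self.p_num_ = model.p_num
        self.selected_ = model.selected
        self.n_features_in_ = X.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        else:
            names = [f"x{i}" for i in range(X.shape[1])]
        pos = {c: j for j, c in enumerate(names)}
        self.coef_ = np.zeros(X.shape[1])
        for k, v in model.b.items():
            self.coef_[pos[k]] = v
        self.intercept_ = model.constant
        t = self.f_star_ if not math.isnan(self.f_star_) else float(grid[-1])
        self.loo_predictions_ = loo_predict(X, y, t)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            X = X[list(self.feature_names_in_)]
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_
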