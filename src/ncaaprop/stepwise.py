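"""Ordinary least squares with per-coefficient F statistics, and F-gated
stepwise predictor selection.

The significance measure used throughout is the square of a coefficient over
its standard error, F_i = (b_i / SD_i)^2 — the squared t statistic of the
coefficient.  A predictor stays in a model only while its F value, computed
in the joint fit, is at or above the current threshold.  With a perfect fit
the residual variance vanishes, the standard errors are zero, and the
statistic is undefined; such fits are flagged and the F values reported as
+infinity so that every predictor trivially passes any threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .components import COMPONENT_KEYS

__all__ = [
    "StepwiseError",
    "FitResult",
    "ols_fit",
    "stepwise_select",
    "StepwiseFRegression",
]

#: Relative tolerance for declaring a fit perfect: sse/n below this fraction
#: of var(y).
PERFECT_FIT_RTOL = 1e-12


class StepwiseError(ValueError):
    pass


@dataclass
class FitResult:
    """Least-squares fit on a predictor subset.

    ``b``, ``sd`` and ``f`` are aligned with ``selected``; ``constant`` is
    the intercept, which is always present and never F-gated.  ``f`` entries
    are ``inf`` when ``perfect_fit`` is set.
    """

    selected: tuple[str, ...]
    b: np.ndarray
    sd: np.ndarray
    f: np.ndarray
    constant: float
    n: int
    sse: float
    perfect_fit: bool = False
    note: str = ""

    @property
    def p_num(self) -> int:
        return len(self.selected)

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Apply the fitted linear model to rows of a design matrix."""
        if isinstance(X, pd.DataFrame):
            Xs = X[list(self.selected)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            Xs = X if X.shape[1] == len(self.selected) else X[:, : len(self.selected)]
        return Xs @ self.b + self.constant if self.selected else np.full(len(X), self.constant)

    def coef_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.selected, self.b)}


def _as_matrix(X, columns: Sequence[str] | None):
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns) if columns is None else list(columns)
        return X[cols].to_numpy(dtype=float), cols
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise StepwiseError("X must be two-dimensional")
    cols = list(columns) if columns is not None else [f"x{i}" for i in range(arr.shape[1])]
    return arr, cols


def _collinear_columns(A: np.ndarray, names: list[str]) -> list[str]:
    """Columns (beyond the intercept) that do not increase the rank."""
    bad, kept = [], A[:, :1]
    for j in range(1, A.shape[1]):
        cand = np.hstack([kept, A[:, j : j + 1]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(kept):
            kept = cand
        else:
            bad.append(names[j - 1])
    return bad


def _fit_subset(Xa: np.ndarray, y: np.ndarray, idx: Sequence[int], names: list[str]) -> FitResult:
    n = len(y)
    p = len(idx)
    sel = tuple(names[j] for j in idx)
    if p == 0:
        const = float(np.mean(y))
        resid = y - const
        sse = float(resid @ resid)
        perfect = sse / n <= PERFECT_FIT_RTOL * max(float(np.var(y)), np.finfo(float).tiny)
        return FitResult(sel, np.empty(0), np.empty(0), np.empty(0), const, n, sse, perfect)
    if n <= p + 1:
        raise StepwiseError(
            f"{p} predictors need more than {p + 1} rows, got {n}"
        )
    A = np.column_stack([np.ones(n), Xa[:, idx]])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        raise StepwiseError(
            f"rank-deficient design; collinear columns: {_collinear_columns(A, list(sel))}"
        )
    resid = y - A @ coef
    sse = float(resid @ resid)
    var_y = max(float(np.var(y)), np.finfo(float).tiny)
    perfect = sse / n <= PERFECT_FIT_RTOL * var_y
    sigma2 = sse / (n - p - 1)
    cov = sigma2 * np.linalg.inv(A.T @ A)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))[1:]
    b = coef[1:]
    if perfect:
        f = np.full(p, np.inf)
    else:
        with np.errstate(divide="ignore"):
            f = np.where(sd > 0, (b / np.where(sd > 0, sd, 1.0)) ** 2, np.inf)
    note = "perfect fit: residual variance ~ 0, F undefined (reported as inf)" if perfect else ""
    return FitResult(sel, b, sd, f, float(coef[0]), n, sse, perfect, note)


def ols_fit(X, y, columns: Sequence[str] | None = None) -> FitResult:
    """Least-squares fit of ``y`` on the given columns of ``X`` plus intercept.

    ``X`` may be a DataFrame (with ``columns`` naming the predictor subset,
    default all) or a 2-D array.  Standard errors use residual variance
    ``sse / (n - p - 1)``; each F value is ``(b_i / SD_i)**2``.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns) if columns is None else list(columns)
        Xa, names = X[cols].to_numpy(dtype=float), cols
    else:
        Xa, names = _as_matrix(X, columns)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != Xa.shape[0]:
        raise StepwiseError("X and y have different numbers of rows")
    return _fit_subset(Xa, y, list(range(Xa.shape[1])), names)


def _prune(Xa, y, idx: list[int], names, threshold: float) -> tuple[list[int], FitResult]:
    """Backward elimination: drop the lowest-F predictor while any F < threshold."""
    idx = list(idx)
    while True:
        fit = _fit_subset(Xa, y, idx, names)
        if not idx or fit.perfect_fit or np.min(fit.f) >= threshold:
            return idx, fit
        worst = int(np.argmin(fit.f))
        del idx[worst]


def _minimize_perfect(Xa, y, idx: list[int], names) -> tuple[list[int], FitResult]:
    """Drop redundant predictors from a perfect fit.

    In a perfect fit every F is infinite, so backward elimination cannot
    remove predictors made redundant once the generating support completed;
    instead, greedily drop any column whose removal keeps the fit perfect.
    """
    from itertools import combinations

    fit = _fit_subset(Xa, y, idx, names)
    all_cols = [j for j in range(Xa.shape[1]) if np.ptp(Xa[:, j]) > 0]
    changed = True
    while changed and len(idx) > 1:
        changed = False
        for k in sorted(idx):
            trial = [j for j in idx if j != k]
            trial_fit = _fit_subset(Xa, y, trial, names)
            if trial_fit.perfect_fit:
                idx, fit, changed = trial, trial_fit, True
                break
        if changed:
            continue
        # replace a pair by a single column when the design admits exact
        # substitutions (e.g. dbl + dblN standing in for dblO)
        for a, b in combinations(sorted(idx), 2):
            for c in all_cols:
                if c in idx:
                    continue
                trial = sorted([j for j in idx if j not in (a, b)] + [c])
                try:
                    trial_fit = _fit_subset(Xa, y, trial, names)
                except StepwiseError:
                    continue
                if trial_fit.perfect_fit:
                    idx, fit, changed = trial, trial_fit, True
                    break
            if changed:
                break
    return idx, fit


def stepwise_select(
    X, y, f_threshold: float, columns: Sequence[str] | None = None
) -> FitResult:
    """F-gated stepwise regression.

    Forward steps try candidate predictors in order of decreasing residual
    sum-of-squares reduction (ties broken by column order); after each
    tentative inclusion, backward elimination removes the lowest-F predictor
    until every retained F is at or above ``f_threshold``.  The search stops
    at a fixpoint: no admissible addition changes the retained set.  Columns
    with zero variance are excluded from candidacy.  If nothing survives the
    gate, the constant-only model (the mean of ``y``) is returned.
    """
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns) if columns is None else list(columns)
        Xa, names = X[cols].to_numpy(dtype=float), cols
    else:
        Xa, names = _as_matrix(X, columns)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n != Xa.shape[0]:
        raise StepwiseError("X and y have different numbers of rows")

    candidates = [j for j in range(Xa.shape[1]) if np.ptp(Xa[:, j]) > 0]
    if not candidates:
        raise StepwiseError("no non-constant predictor columns")

    selected: list[int] = []
    current = _fit_subset(Xa, y, selected, names)
    seen = {frozenset()}
    sse_scale = max(current.sse, np.finfo(float).tiny)
    tol = 1e-12 * sse_scale

    while True:
        trials = []
        for j in candidates:
            if j in selected or n <= len(selected) + 2:
                continue
            try:
                fit_j = _fit_subset(Xa, y, selected + [j], names)
            except StepwiseError:
                continue
            trials.append((fit_j.sse, j))
        trials.sort(key=lambda t: (t[0], t[1]))
        moved = False
        for sse_j, j in trials:
            if sse_j >= current.sse - tol:
                break  # sorted: no remaining candidate improves the fit
            pruned_idx, pruned_fit = _prune(Xa, y, selected + [j], names, f_threshold)
            key = frozenset(pruned_idx)
            if key in seen:
                continue
            seen.add(key)
            selected, current = pruned_idx, pruned_fit
            moved = True
            break
        if not moved:
            break

    final_idx, final_fit = _prune(Xa, y, selected, names, f_threshold)
    if final_fit.perfect_fit and final_idx:
        final_idx, final_fit = _minimize_perfect(Xa, y, final_idx, names)
    return final_fit


class StepwiseFRegression(RegressorMixin, BaseEstimator):
    """F-gated stepwise linear regression in scikit-learn estimator form.

    Parameters
    ----------
    f_threshold : float, default 2.0
        Minimum per-coefficient F value, ``(b/SD)**2``, for a predictor to
        stay in the model.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Coefficients over all input features; zero outside the support.
    intercept_ : float
    support_ : boolean ndarray of shape (n_features,)
    selected_ : tuple of retained feature names
    f_values_, coef_sd_ : ndarray over input features (NaN outside support)
    sse_ : residual sum of squares of the final fit
    perfect_fit_ : bool
    result_ : the underlying :class:`FitResult`
    """

    def __init__(self, f_threshold: float = 2.0):
        self.f_threshold = f_threshold

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
        else:
            names = None
        Xv, yv = check_X_y(X, y, dtype=float, ensure_min_samples=3)
        self.n_features_in_ = Xv.shape[1]
        if names is not None:
            self.feature_names_in_ = np.asarray(names, dtype=object)
        else:
            names = [f"x{i}" for i in range(Xv.shape[1])]
        result = stepwise_select(Xv, yv, self.f_threshold, columns=names)
        pos = {name: i for i, name in enumerate(names)}
        self.coef_ = np.zeros(Xv.shape[1])
        self.f_values_ = np.full(Xv.shape[1], np.nan)
        self.coef_sd_ = np.full(Xv.shape[1], np.nan)
        self.support_ = np.zeros(Xv.shape[1], dtype=bool)
        for k, name in enumerate(result.selected):
            j = pos[name]
            self.coef_[j] = result.b[k]
            self.f_values_[j] = result.f[k]
            self.coef_sd_[j] = result.sd[k]
            self.support_[j] = True
        self.intercept_ = result.constant
        self.sse_ = result.sse
        self.perfect_fit_ = result.perfect_fit
        self.selected_ = result.selected
        self.result_ = result
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            X = X[list(self.feature_names_in_)]
        Xv = check_array(X, dtype=float)
        return Xv @ self.coef_ + self.intercept_


def component_frame(X) -> pd.DataFrame:
    """Coerce an array or frame to a DataFrame with the 13 component columns."""
    if isinstance(X, pd.DataFrame):
        return X[list(COMPONENT_KEYS)]
    return pd.DataFrame(np.asarray(X), columns=list(COMPONENT_KEYS))
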