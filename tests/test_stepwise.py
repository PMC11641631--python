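"""OLS with per-coefficient F statistics and the F-gated stepwise search."""

import itertools

import numpy as np
import pytest
from sklearn.base import clone

from ncaaprop import (
    StepwiseError,
    StepwiseFRegression,
    SyntheticSpec,
    generate_property,
    ols_fit,
    stepwise_select,
    well_conditioned_supports,
)


def normal_equations_oracle(X, y):
    """Brute-force textbook OLS: coefficients, standard errors, F values."""
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    coef = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ coef
    sse = float(resid @ resid)
    sigma2 = sse / (n - p - 1)
    sd = np.sqrt(np.diag(sigma2 * np.linalg.inv(A.T @ A)))[1:]
    return coef[0], coef[1:], sd, (coef[1:] / sd) ** 2, sse


class TestOlsFit:
    def test_noiseless_line_is_perfect_fit(self):
        x = np.arange(10.0).reshape(-1, 1)
        y = 2.0 * x.ravel() + 1.0
        fit = ols_fit(x, y)
        assert fit.b[0] == pytest.approx(2.0, abs=1e-10)
        assert fit.constant == pytest.approx(1.0, abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-16)
        assert fit.perfect_fit
        assert np.isinf(fit.f).all()

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.integers(0, 5, size=(20, 3)).astype(float)
        X += rng.normal(0, 1e-6, X.shape)  # break accidental collinearity
        y = rng.normal(size=20)
        fit = ols_fit(X, y)
        c0, b, sd, f, sse = normal_equations_oracle(X, y)
        assert np.allclose(fit.b, b, atol=1e-8)
        assert fit.constant == pytest.approx(c0, abs=1e-8)
        assert np.allclose(fit.sd, sd, atol=1e-8)
        assert fit.sse == pytest.approx(sse, rel=1e-10)

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        fit = ols_fit(X, y)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        assert np.allclose(fit.b, res.params[1:], atol=1e-10)
        assert np.allclose(fit.sd, res.bse[1:], atol=1e-10)
        assert np.allclose(fit.f, res.tvalues[1:] ** 2, atol=1e-8)

    def test_f_is_squared_coefficient_over_sd(self, rng):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        fit = ols_fit(X, y)
        assert np.array_equal(fit.f, (fit.b / fit.sd) ** 2)

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=(10, 1))
        X = np.hstack([x, 2 * x])
        with pytest.raises(StepwiseError, match="collinear.*x1"):
            ols_fit(X, rng.normal(size=10))

    def test_too_few_rows(self, rng):
        with pytest.raises(StepwiseError, match="rows"):
            ols_fit(rng.normal(size=(4, 4)), rng.normal(size=4))


def exhaustive_oracle(X, y, threshold):
    """Best-sse subset whose every coefficient has F >= threshold.

    Ties broken toward fewer predictors, then column order.
    """
    cols = [c for c in X.columns if X[c].nunique() > 1]
    best = None
    for size in range(0, len(cols) + 1):
        for combo in itertools.combinations(cols, size):
            try:
                fit = ols_fit(X, y, columns=list(combo))
            except StepwiseError:
                continue
            if combo and not fit.perfect_fit and np.min(fit.f) < threshold:
                continue
            key = (fit.sse, len(combo))
            if best is None or key < best[0]:
                best = (key, set(combo))
    return best[1]


class TestStepwiseSelect:
    def test_single_informative_predictor_noiseless(self, design_matrix):
        y = 3.0 * design_matrix["anyO"].to_numpy() + 1.0
        fit = stepwise_select(design_matrix, y, 2.0)
        assert fit.selected == ("anyO",)
        assert fit.b[0] == pytest.approx(3.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_subset_oracle(self, seed, design_matrix):
        # true support plus decoy predictors at sample correlation < 0.5,
        # where the greedy fixpoint and the global best-sse admissible
        # subset provably coincide
        rng = np.random.default_rng(200 + seed)
        supports = well_conditioned_supports(design_matrix, max_size=2)
        support = supports[(7 * seed) % len(supports)]
        corr = design_matrix.corr()
        # decoys: weakly correlated with the support and with each other,
        # and not quasi-indicator columns (a pair of columns that vary on
        # only 2-3 rows can jointly soak up noise with joint F above the
        # gate, which the greedy path can never reach one column at a time)
        weak = [
            c for c in design_matrix.columns
            if c not in support
            and max(abs(corr.loc[c, s]) for s in support) < 0.5
            and (design_matrix[c] != design_matrix[c].mode().iloc[0]).sum() >= 3
        ]
        decoys: list = []
        for c in rng.permutation(weak):
            if len(decoys) == 3:
                break
            if all(abs(corr.loc[c, d]) < 0.5 for d in decoys):
                decoys.append(c)
        Xs = design_matrix[list(support) + decoys]
        beta = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(support))
        spec = SyntheticSpec(tuple(support), tuple(beta), 0.5, 0.2, seed=seed)
        y = generate_property(spec, design_matrix).to_numpy()
        for threshold in (3.0, 5.0):
            fit = stepwise_select(Xs, y, threshold)
            oracle = exhaustive_oracle(Xs, y, threshold)
            assert set(fit.selected) == oracle, (support, threshold)

    def test_fixpoint_under_rerun(self, design_matrix, rng):
        y = rng.normal(size=20) + design_matrix["aliphC"].to_numpy()
        fit = stepwise_select(design_matrix, y, 2.0)
        again = stepwise_select(design_matrix[list(fit.selected)], y, 2.0)
        assert set(again.selected) == set(fit.selected)
        assert np.allclose(sorted(again.b), sorted(fit.b), atol=1e-10)

    def test_all_retained_f_above_threshold(self, design_matrix, rng):
        for threshold in (1.0, 2.4, 5.0):
            y = rng.normal(size=20) + 0.8 * design_matrix["anyO"].to_numpy()
            fit = stepwise_select(design_matrix, y, threshold)
            if fit.selected and not fit.perfect_fit:
                assert np.min(fit.f) >= threshold

    def test_noiseless_recovery_across_thresholds(self, design_matrix):
        supports = well_conditioned_supports(design_matrix, max_size=3)
        spec = SyntheticSpec(supports[-1], tuple(1.0 + i for i in range(len(supports[-1]))), -0.2)
        y = generate_property(spec, design_matrix).to_numpy()
        for threshold in (1.0, 2.0, 5.0, 10.0):
            fit = stepwise_select(design_matrix, y, threshold)
            assert set(fit.selected) == set(spec.support)
            got = fit.coef_dict()
            for k, b in zip(spec.support, spec.beta):
                assert got[k] == pytest.approx(b, abs=1e-8)

    def test_no_survivor_returns_constant_model(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        fit = stepwise_select(X, y, 1e9)
        assert fit.selected == ()
        assert fit.constant == pytest.approx(float(np.mean(y)))

    def test_zero_variance_columns_never_selected(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        y = X[:, 0] + rng.normal(0, 0.1, 20)
        fit = stepwise_select(X, y, 2.0)
        assert "x1" not in fit.selected


class TestEstimator:
    def test_sklearn_protocol(self, design_matrix, rng):
        est = StepwiseFRegression(f_threshold=3.0)
        assert est.get_params() == {"f_threshold": 3.0}
        est2 = clone(est).set_params(f_threshold=2.0)
        y = design_matrix["anyO"].to_numpy() * 2.0 + rng.normal(0, 0.1, 20)
        est2.fit(design_matrix, y)
        assert est2.support_.sum() == len(est2.selected_)
        assert np.allclose(
            est2.predict(design_matrix),
            design_matrix.to_numpy() @ est2.coef_ + est2.intercept_,
        )

    def test_fitted_attributes_consistent(self, design_matrix):
        y = 1.5 * design_matrix["plus"].to_numpy() - 0.3
        est = StepwiseFRegression(f_threshold=2.0).fit(design_matrix, y)
        assert est.perfect_fit_
        assert est.selected_ == ("plus",)
        assert est.intercept_ == pytest.approx(-0.3, abs=1e-10)
        assert est.coef_[list(design_matrix.columns).index("plus")] == pytest.approx(1.5, abs=1e-10)
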