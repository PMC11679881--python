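"""PLS/OPLS models, VIP, decision rules and validation."""

import numpy as np
import pandas as pd
import pytest

from shetca.latent import (
    ModelKind,
    Scaling,
    classify_by_coefficients,
    classify_by_vip,
    cv_anova,
    diagnostics,
    fit_opls,
    fit_pls,
    p_corr,
    permutation_test,
    scale_matrix,
    select_components,
    vip,
)


def make_signal_data(seed=0, n=69, p=43, n_informative=20, noise=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    b = np.zeros(p)
    b[:n_informative] = rng.uniform(0.5, 1.5, n_informative)
    y = X @ b + rng.normal(0, noise, n)
    return X, y, b


class TestScaling:
    def test_uv_gives_zero_mean_unit_sd(self, rng):
        X = rng.normal(3, 5, size=(30, 4))
        Xs = scale_matrix(X, Scaling.UV)
        assert np.allclose(Xs.values.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(Xs.values.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_pareto_sd_is_sqrt_of_original(self):
        col = np.array([0.0, 4.0, 8.0, 12.0, 16.0])
        sd = col.std(ddof=1)
        Xs = scale_matrix(col[:, None], Scaling.PARETO)
        assert np.allclose(Xs.values.std(axis=0, ddof=1), np.sqrt(sd))

    def test_centered_unit_variance_column_unchanged_under_uv(self):
        col = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0.0, 1.0], ddof=1)
        Xs = scale_matrix(col[:, None], Scaling.UV)
        assert np.allclose(Xs.values.ravel(), col)

    def test_constant_columns_dropped(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        Xs = scale_matrix(X, Scaling.UV)
        assert Xs.columns == ["a"] and Xs.dropped_columns == ["b"]


class TestPLS:
    def test_noiseless_linear_response_fully_explained(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 8))
        y = X @ rng.uniform(0.5, 1.5, 8)
        model = fit_pls(scale_matrix(X), y, 8)
        assert model.r2y > 1 - 1e-9
        yhat = model.predict_scaled(scale_matrix(X).values)
        assert np.allclose(yhat, y, atol=1e-6)

    def test_one_component_coefficients_along_xty(self, rng):
        X = rng.normal(size=(50, 6))
        y = rng.normal(size=50)
        Xs = scale_matrix(X, Scaling.UV)
        model = fit_pls(Xs, y, 1)
        direction = Xs.values.T @ (y - y.mean())
        cos = np.dot(model.coefficients, direction) / (
            np.linalg.norm(model.coefficients) * np.linalg.norm(direction))
        assert abs(cos - 1) < 1e-10

    def test_informative_coefficient_signs_recovered(self):
        X, y, b = make_signal_data(seed=42)
        model = fit_pls(scale_matrix(X), y, 3)
        informative = b != 0
        assert np.all(np.sign(model.coefficients[informative]) == np.sign(b[informative]))

    def test_rank_exceeded_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="rank"):
            fit_pls(scale_matrix(X), rng.normal(size=5), 4)

    def test_matches_sklearn_reference(self, rng):
        """Dual-route check against an established PLS implementation."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y, _ = make_signal_data(seed=7)
        Xs = scale_matrix(X, Scaling.UV)
        model = fit_pls(Xs, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(Xs.values, y)
        assert np.allclose(model.coefficients, ref.coef_.ravel(), atol=1e-10)


class TestOPLS:
    def test_zero_orthogonal_equals_one_component_pls(self):
        X, y, _ = make_signal_data(seed=5)
        Xs = scale_matrix(X)
        pls1 = fit_pls(Xs, y, 1)
        opls0 = fit_opls(Xs, y, 0)
        assert np.allclose(
            pls1.predict_scaled(Xs.values), opls0.predict_scaled(Xs.values), atol=1e-10)

    def test_predictive_and_orthogonal_scores_uncorrelated(self):
        X, y, _ = make_signal_data(seed=5)
        model = fit_opls(scale_matrix(X), y, 4)
        t = model.scores[:, 0]
        for a in range(model.n_orthogonal):
            r = np.corrcoef(t, model.orthogonal_scores[:, a])[0, 1]
            assert abs(r) <= 1e-8

    def test_orthogonal_block_improves_predictive_fit(self):
        rng = np.random.default_rng(11)
        n = 60
        t_signal = rng.normal(size=n)
        t_orth = rng.normal(size=n)
        X = np.hstack([
            np.outer(t_signal, rng.uniform(0.5, 1, 5)) + 0.05 * rng.normal(size=(n, 5)),
            np.outer(t_orth, rng.uniform(0.5, 1, 5)) + 0.05 * rng.normal(size=(n, 5)),
        ])
        y = t_signal + 0.1 * rng.normal(size=n)
        Xs = scale_matrix(X)
        pls1 = fit_pls(Xs, y, 1)
        opls = fit_opls(Xs, y, 1)
        assert opls.r2y >= pls1.r2y - 1e-12
        orth_variance = np.sum((opls.orthogonal_scores @ opls.orthogonal_loadings.T) ** 2)
        assert orth_variance > 0


class TestSelectComponents:
    def test_pure_noise_keeps_few_components(self, rng):
        X = rng.normal(size=(50, 20))
        y = rng.normal(size=50)
        k = select_components(scale_matrix(X), y, ModelKind.PLS)
        assert k <= 1
        assert fit_pls(scale_matrix(X), y, k).q2 <= 0.05

    def test_strong_two_factor_signal_keeps_at_least_two(self):
        # unequal factor weights: the first weight vector cannot align
        # with y, so a second component is required
        rng = np.random.default_rng(2)
        n = 60
        t1, t2 = rng.normal(size=n), rng.normal(size=n)
        X = np.hstack([
            np.outer(t1, rng.uniform(0.5, 1, 6)),
            np.outer(t2, rng.uniform(0.5, 1, 6)),
        ]) + 0.02 * rng.normal(size=(n, 12))
        y = t1 + 2.0 * t2 + 0.05 * rng.normal(size=n)
        assert select_components(scale_matrix(X), y, ModelKind.PLS) >= 2

    def test_deterministic(self):
        X, y, _ = make_signal_data(seed=9)
        Xs = scale_matrix(X)
        assert select_components(Xs, y, ModelKind.PLS) == select_components(Xs, y, ModelKind.PLS)


class TestVIPAndPCorr:
    def test_vip_normalisation_identity(self):
        X, y, _ = make_signal_data(seed=1)
        for model in (fit_pls(scale_matrix(X), y, 3), fit_opls(scale_matrix(X), y, 2)):
            v = vip(model)
            assert np.isclose(np.sum(v**2), X.shape[1], atol=1e-9)

    def test_single_informative_variable_dominates(self, rng):
        X = rng.normal(size=(50, 8))
        y = 3 * X[:, 4] + 0.01 * rng.normal(size=50)
        model = fit_pls(scale_matrix(X), y, 1)
        assert np.argmax(vip(model)) == 4

    def test_identical_columns_share_unit_vip(self, rng):
        t = rng.normal(size=40)
        X = np.column_stack([t, t, t])
        y = t + 0.01 * rng.normal(size=40)
        model = fit_pls(scale_matrix(X), y, 1)
        assert np.allclose(vip(model), 1.0)

    def test_p_corr_matches_brute_force(self, rng):
        X, y, _ = make_signal_data(seed=4)
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 2)
        pc = p_corr(model, Xs)
        assert np.all(np.abs(pc) <= 1 + 1e-12)
        t = model.scores[:, 0]
        for j in (0, 10, 42):
            assert pc[j] == pytest.approx(np.corrcoef(t, Xs.values[:, j])[0, 1], abs=1e-12)

    def test_column_equal_to_score_has_unit_p_corr(self, rng):
        X, y, _ = make_signal_data(seed=4)
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 1)
        Xs2 = scale_matrix(np.column_stack([model.scores[:, 0], X[:, 1]]))
        pc = p_corr(model, Xs2)
        assert pc[0] == pytest.approx(1.0, abs=1e-12)


class TestDecisionRules:
    def _toy_model(self):
        rng = np.random.default_rng(8)
        n = 40
        t = rng.normal(size=n)
        X = np.column_stack([
            t + 0.05 * rng.normal(size=n),        # positive coeff, positive corr
            -t + 0.05 * rng.normal(size=n),       # negative both
            0.02 * t + rng.normal(size=n),        # weak
        ])
        y = t
        Xs = scale_matrix(X)
        return fit_pls(Xs, y, 1), Xs

    def test_coefficient_rule_requires_both_positive(self):
        model, Xs = self._toy_model()
        calls = classify_by_coefficients(model, Xs)
        pc = p_corr(model, Xs)
        expected = np.where((model.coefficients > 0) & (pc > 0), "ACTIVE", "INACTIVE")
        assert list(calls) == list(expected)
        assert calls.iloc[0] == "ACTIVE" and calls.iloc[1] == "INACTIVE"

    def test_vip_rule_and_strict_threshold(self):
        model, Xs = self._toy_model()
        v = vip(model)
        pc = p_corr(model, Xs)
        calls = classify_by_vip(model, Xs, threshold=0.6)
        expected = np.where((v > 0.6) & (pc > 0), "ACTIVE", "INACTIVE")
        assert list(calls) == list(expected)
        # a variable sitting exactly at the threshold is NOT active
        at_boundary = classify_by_vip(model, Xs, threshold=float(v[0]))
        assert at_boundary.iloc[0] == "INACTIVE"


class TestValidation:
    def test_permutation_separates_signal_from_null(self):
        X, y, _ = make_signal_data(seed=10)
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 2)
        perm = permutation_test(Xs, y, model, n_permutations=50, seed=3)
        assert perm.valid
        assert perm.permuted_q2.mean() < perm.original_q2
        rng = np.random.default_rng(99)
        y_null = rng.normal(size=len(y))
        null_model = fit_pls(Xs, y_null, 2)
        null_perm = permutation_test(Xs, y_null, null_model, n_permutations=50, seed=3)
        assert null_model.q2 <= null_perm.permuted_q2.max() + 0.1

    def test_permutation_reproducible_under_seed(self):
        X, y, _ = make_signal_data(seed=10)
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 1)
        a = permutation_test(Xs, y, model, n_permutations=10, seed=5)
        b = permutation_test(Xs, y, model, n_permutations=10, seed=5)
        assert np.array_equal(a.permuted_q2, b.permuted_q2)

    def test_perfect_fit_has_zero_rmsee(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ np.ones(5)
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 5)
        report = diagnostics(model, Xs, y)
        assert report.rmsee == pytest.approx(0.0, abs=1e-9)

    def test_injected_outlier_exceeds_t2_limit(self):
        X, y, _ = make_signal_data(seed=6, n=50, p=10, n_informative=5)
        X[0] += 30.0  # extreme observation
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 2)
        report = diagnostics(model, Xs, y)
        assert report.hotelling_t2[0] > report.t2_limit

    def test_cv_scores_track_scores_on_stable_data(self):
        X, y, _ = make_signal_data(seed=12, n=80, p=10, n_informative=8, noise=0.1)
        Xs = scale_matrix(X)
        model = fit_pls(Xs, y, 1)
        t = model.scores[:, 0]
        span = t.max() - t.min()
        assert np.max(np.abs(model.cv_scores - t)) < 0.25 * span

    def test_cv_anova_signal_vs_null_and_monotone(self):
        rng = np.random.default_rng(13)
        n, p = 60, 15
        X = rng.normal(size=(n, p))
        b = np.zeros(p)
        b[:5] = 1.0
        noise = rng.normal(size=n)
        pvals = []
        for strength in (0.0, 0.5, 2.0):
            y = strength * (X @ b) + noise
            Xs = scale_matrix(X)
            model = fit_pls(Xs, y, 2)
            _, pv = cv_anova(model, y)
            pvals.append(pv)
        assert pvals[0] > 0.05          # pure noise
        assert pvals[2] < 0.05          # strong signal
        assert pvals[0] >= pvals[1] >= pvals[2]
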