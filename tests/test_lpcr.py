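import json

import numpy as np
import pytest

from radpcr.errors import FitError, StatsError
from radpcr.lpcr import (
    ConfusionDiagnostics,
    auc,
    confusion_diagnostics,
    cross_validate,
    default_lambda_grid,
    fit_penalized_logistic,
    fit_unpenalized_logistic,
    penalized_objective,
    roc_with_ci,
    variable_importance,
)


def logistic_data(rng, n=60, p=3, beta=None, intercept=-0.2):
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(p, 3)] = [1.0, -0.5, 0.0][: min(p, 3)]
    beta = np.asarray(beta, dtype=float)
    eta = intercept + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    if len(np.unique(y)) < 2:  # pragma: no cover - rng dependent
        y[0], y[1] = 0, 1
    return X, y


class TestGrid:
    def test_default_grid(self):
        grid = default_lambda_grid()
        assert len(grid) == 61
        assert grid[0] == 0.0
        assert grid[-1] == 3.0
        np.testing.assert_allclose(np.diff(grid), 0.05)


class TestPenalizedFit:
    def test_full_shrinkage_closed_form(self, rng):
        X, y = logistic_data(rng, n=50)
        n = len(y)
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        lam_max = np.abs(Xs.T @ (y - y.mean())).max() / n
        fit = fit_penalized_logistic(X, y, lam=lam_max * 1.01, alpha=1.0)
        np.testing.assert_array_equal(fit.coefficients, 0.0)
        pbar = y.mean()
        assert fit.intercept == pytest.approx(np.log(pbar / (1 - pbar)), abs=1e-6)

    def test_lambda_zero_matches_mle_oracle(self, rng):
        import statsmodels.api as sm  # independent second-order solver

        X, y = logistic_data(rng, n=40, p=3)
        fit = fit_penalized_logistic(X, y, lam=0.0, alpha=1.0)
        res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
        assert fit.intercept == pytest.approx(res.params[0], abs=1e-4)
        np.testing.assert_allclose(fit.coefficients, res.params[1:], atol=1e-4)

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_beats_exhaustive_grid_oracle(self, alpha):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1])
        lam = 0.3
        fit = fit_penalized_logistic(
            X, y, lam=lam, alpha=alpha, standardize=False, fit_intercept=False
        )
        b1, b2 = np.meshgrid(np.linspace(-5, 5, 201), np.linspace(-5, 5, 201))
        B = np.column_stack([b1.ravel(), b2.ravel()])
        objs = np.array(
            [penalized_objective(X @ b, y, b, lam, alpha) for b in B]
        )
        assert fit.objective <= objs.min() + 1e-12

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(FitError):
            fit_penalized_logistic(X, np.ones(10), lam=0.1)

    def test_nonfinite_rejected(self):
        X = np.array([[1.0, np.inf], [0.0, 1.0]])
        with pytest.raises(FitError):
            fit_penalized_logistic(X, np.array([0, 1]), lam=0.1)

    def test_sparsity_monotone_along_grid(self, rng):
        X, y = logistic_data(rng, n=60, p=8, beta=[2, -1.5, 1, 0.5, 0, 0, 0, 0])
        nnz = []
        for lam in default_lambda_grid():
            fit = fit_penalized_logistic(X, y, lam=float(lam), alpha=1.0)
            nnz.append(int((np.abs(fit.coefficients) > 1e-10).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_alpha_bracketing_objective(self, rng):
        # attained optimum is monotone in alpha when solution coefs are small
        X, y = logistic_data(rng, n=50, p=4, beta=[0.8, -0.6, 0.3, 0.0])
        lam = 0.2
        vals = [
            fit_penalized_logistic(X, y, lam=lam, alpha=a).objective
            for a in (0.0, 0.5, 1.0)
        ]
        assert vals[0] <= vals[1] + 1e-10
        assert vals[1] <= vals[2] + 1e-10


class TestUnpenalizedFit:
    def test_binary_predictor_log_odds_ratio(self):
        # 2x2 table oracle: x=1: 8 pos / 4 neg ; x=0: 3 pos / 9 neg
        x = np.r_[np.ones(12), np.zeros(12)]
        y = np.r_[np.ones(8), np.zeros(4), np.ones(3), np.zeros(9)]
        fit = fit_unpenalized_logistic(x[:, None], y)
        log_or = np.log((8 * 9) / (4 * 3))
        assert fit.coefficients[0] == pytest.approx(log_or, abs=1e-6)

    def test_constant_predictor(self):
        x = np.ones((20, 1))
        y = np.r_[np.ones(5), np.zeros(15)]
        fit = fit_unpenalized_logistic(x, y)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.intercept == pytest.approx(np.log(5 / 15), abs=1e-6)

    def test_three_predictors_routed_away(self, rng):
        X, y = logistic_data(rng, n=30, p=3)
        with pytest.raises(FitError, match="penalized"):
            fit_unpenalized_logistic(X, y)


class TestAUC:
    def test_perfect_ranking(self):
        y = np.array([0, 1, 0, 1])
        assert auc(y.astype(float), y) == 1.0

    def test_all_ties(self):
        assert auc(np.ones(10), np.r_[np.ones(4), np.zeros(6)]) == 0.5

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(5):
            scores = rng.choice([0.1, 0.2, 0.3, 0.5, 0.9], size=30)
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                labels[0] = 1 - labels[0]
            total = 0.0
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            for sp in pos:  # brute-force enumeration over all pairs
                for sn in neg:
                    total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
            expected = total / (len(pos) * len(neg))
            assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_complement_identity(self, rng):
        scores = rng.normal(size=40)  # tie-free a.s.
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(StatsError):
            auc(np.arange(4.0), np.ones(4))


class TestCrossValidate:
    def test_separable_signal(self, rng):
        y = rng.integers(0, 2, size=100)
        y[:2] = [0, 1]
        X = np.column_stack([2.0 * y - 1.0 + 0.01 * rng.normal(size=100)])
        cv = cross_validate(X, y, grid=np.array([0.0, 0.5]), k=5, L=5, rng_seed=0)
        assert cv.mean_auc[0] >= 0.99

    def test_permutation_null_band(self, rng):
        rng = np.random.default_rng(2024)
        X = rng.normal(size=(100, 10))
        y = rng.permutation(np.r_[np.ones(50), np.zeros(50)]).astype(int)
        cv = cross_validate(X, y, k=5, L=20, rng_seed=1)
        assert 0.40 <= cv.optimal_auc <= 0.60

    def test_bit_reproducible(self, rng):
        X, y = logistic_data(rng, n=40, p=4)
        grid = np.array([0.0, 0.1, 0.5])
        a = cross_validate(X, y, grid=grid, k=4, L=3, rng_seed=77)
        b = cross_validate(X, y, grid=grid, k=4, L=3, rng_seed=77)
        assert json.dumps(a.to_dict()) == json.dumps(b.to_dict())
        np.testing.assert_array_equal(a.repeat_auc, b.repeat_auc)

    def test_tie_breaks_to_larger_lambda(self, rng):
        X = rng.normal(size=(40, 3))  # pure noise: long plateau at 0.5
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        cv = cross_validate(X, y, k=5, L=2, rng_seed=0)
        plateau = cv.mean_auc == cv.mean_auc.max()
        assert cv.optimal_lambda == cv.grid[np.where(plateau)[0][-1]]

    def test_n_too_small(self, rng):
        X, y = logistic_data(rng, n=8, p=2)
        with pytest.raises(FitError):
            cross_validate(X, y, k=5, L=1)

    def test_curve_in_unit_interval(self, rng):
        X, y = logistic_data(rng, n=40, p=4)
        cv = cross_validate(X, y, grid=np.array([0.0, 0.2, 1.0]), k=5, L=4, rng_seed=5)
        assert np.all(cv.mean_auc >= 0.0) and np.all(cv.mean_auc <= 1.0)
        assert cv.optimal_lambda in cv.grid


class TestVariableImportance:
    def test_single_nonzero(self):
        fit = _manual_fit([0.0, 1.7, 0.0], [1.0, 1.0, 1.0], ["a", "b", "c"])
        imp = dict(variable_importance(fit))
        assert imp == {"b": 100.0, "a": 0.0, "c": 0.0}

    def test_linear_scale(self):
        fit = _manual_fit([2.0, 1.0], [1.0, 1.0], ["a", "b"])
        imp = dict(variable_importance(fit))
        assert imp["a"] == 100.0
        assert imp["b"] == pytest.approx(50.0)

    def test_standardization_enters_score(self):
        # coef 1 on a scale-10 feature outweighs coef 5 on a scale-1 feature
        fit = _manual_fit([1.0, 5.0], [10.0, 1.0], ["wide", "narrow"])
        imp = dict(variable_importance(fit))
        assert imp["wide"] == 100.0
        assert imp["narrow"] == 50.0

    def test_all_zero_warns(self, caplog):
        fit = _manual_fit([0.0, 0.0], [1.0, 1.0], ["a", "b"])
        with caplog.at_level("WARNING"):
            imp = variable_importance(fit)
        assert all(s == 0.0 for _, s in imp)
        assert any("zero" in r.message for r in caplog.records)

    def test_planted_covariate_ranks_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 120
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            X = rng.normal(size=(n, 6))
            X[:, 2] = 2.0 * y + rng.normal(size=n)  # planted strong covariate
            fit = fit_penalized_logistic(X, y.astype(int), lam=0.05, alpha=1.0)
            ranking = variable_importance(fit)
            if ranking[0][0] == "x2":
                hits += 1
        assert hits >= 18


def _manual_fit(coefs, scales, names):
    from radpcr.lpcr import PenalizedLogisticFit

    coefs = np.asarray(coefs, dtype=float)  # original-scale coefficients
    scales = np.asarray(scales, dtype=float)
    return PenalizedLogisticFit(
        intercept=0.0,
        coefficients=coefs,
        lam=0.1,
        alpha=1.0,
        feature_names=list(names),
        feature_means=np.zeros_like(coefs),
        feature_scales=scales,
        n_iter=1,
        converged=True,
        objective=0.0,
    )


class TestROC:
    def test_perfect_classifier(self):
        labels = np.r_[np.ones(8), np.zeros(12)].astype(int)
        scores = labels.astype(float)
        roc = roc_with_ci(scores, labels, n_boot=200, rng_seed=0)
        assert roc.auc == 1.0
        assert roc.ci95 == (1.0, 1.0)
        assert any((f == 0.0 and t == 1.0) for f, t in zip(roc.fpr, roc.tpr))

    def test_auc_field_consistent(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        roc = roc_with_ci(scores, labels, n_boot=100, rng_seed=1)
        assert roc.auc == pytest.approx(auc(scores, labels), abs=1e-12)

    def test_monotone_curve(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        roc = roc_with_ci(scores, labels, n_boot=50, rng_seed=2)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_bootstrap_coverage(self):
        # binormal model: true AUC = Phi(mu / sqrt(2))
        from scipy.stats import norm

        mu = 1.0
        true_auc = norm.cdf(mu / np.sqrt(2))
        covered = 0
        n_sims = 200
        for sim in range(n_sims):
            rng = np.random.default_rng(10_000 + sim)
            scores = np.r_[rng.normal(mu, 1, 20), rng.normal(0, 1, 20)]
            labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
            roc = roc_with_ci(scores, labels, n_boot=400, rng_seed=sim)
            if roc.ci95[0] <= true_auc <= roc.ci95[1]:
                covered += 1
        assert covered >= 0.92 * n_sims


class TestConfusion:
    def test_perfect_scores(self):
        labels = np.array([1, 1, 0, 0])
        diag = confusion_diagnostics(labels.astype(float), labels)
        assert diag.sensitivity == 1.0 and diag.specificity == 1.0

    def test_all_below_threshold(self):
        labels = np.array([1, 1, 0, 0])
        diag = confusion_diagnostics(np.full(4, 0.4), labels)
        assert diag.sensitivity == 0.0
        assert diag.tp + diag.fp == 0

    def test_arithmetic_oracle(self):
        diag = ConfusionDiagnostics(tp=3, fp=1, tn=5, fn=2)
        assert diag.sensitivity == pytest.approx(0.6)
        assert diag.specificity == pytest.approx(5 / 6)
        assert diag.ppv == pytest.approx(3 / 4)
        assert diag.npv == pytest.approx(5 / 7)
        assert diag.accuracy == pytest.approx(8 / 11)
        assert diag.n == 11

    def test_counts_sum_to_n(self, rng):
        scores = rng.random(25)
        labels = rng.integers(0, 2, size=25)
        diag = confusion_diagnostics(scores, labels, threshold=0.3)
        assert diag.n == 25

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            confusion_diagnostics(np.array([0.5]), np.array([1]), threshold=1.5)
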