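import numpy as np
import pytest
import statsmodels.api as sm

from methclock.build import (
    FitOptions,
    build_clock,
    fit_clock,
    impute_missing,
    select_lambda,
)
from methclock.core import BetaMatrix, TransformSpec, ValidationError
from methclock.simulate import SimConfig, simulate_cohort

from conftest import make_betas, make_sheet


def _toy_regression(seed=0, n=50, p=3, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, p))
    beta = np.zeros(p)
    beta[:3] = [1.5, -2.0, 0.7][: min(p, 3)]
    y = 0.3 + X @ beta + rng.normal(0, noise, n)
    return X, y


def elastic_net_objective(X, y, intercept, beta, lam, alpha):
    n = len(y)
    resid = y - intercept - X @ beta
    return (
        0.5 / n * np.sum(resid**2)
        + lam * (alpha * np.abs(beta).sum() + 0.5 * (1 - alpha) * np.sum(beta**2))
    )


class TestFitOptions:
    def test_alpha_bounds(self):
        with pytest.raises(ValidationError):
            FitOptions(alpha=1.5)

    def test_min_folds(self):
        with pytest.raises(ValidationError):
            FitOptions(n_folds=2)

    def test_bad_rule(self):
        with pytest.raises(ValidationError):
            FitOptions(lambda_rule="median")


class TestSelectLambda:
    def test_constant_y_rejected(self):
        X, _ = _toy_regression()
        with pytest.raises(ValidationError, match="constant"):
            select_lambda(X, np.ones(50), FitOptions(n_folds=5))

    def test_too_few_samples(self):
        X, y = _toy_regression(n=5)
        with pytest.raises(ValidationError, match="n_folds"):
            select_lambda(X, y, FitOptions(n_folds=10))

    def test_deterministic_for_seed(self):
        X, y = _toy_regression(seed=3, n=60, p=20)
        opts = FitOptions(n_folds=5, seed=11)
        a = select_lambda(X, y, opts)
        b = select_lambda(X, y, opts)
        assert a.lambda_opt == b.lambda_opt
        assert np.array_equal(a.mean_cv_error, b.mean_cv_error)

    def test_pure_noise_selects_large_lambda(self):
        # With no signal, CV should favor heavy penalization: lambda_opt in
        # the top of the path and an (almost) empty model at that lambda.
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(80, 200))
        y = rng.normal(0, 1, 80)
        opts = FitOptions(n_folds=5, seed=1)
        sel = select_lambda(X, y, opts)
        rank = int(np.argmin(np.abs(sel.lambdas - sel.lambda_opt)))
        assert rank <= 20  # near the path maximum (index 0 = largest)
        clock = fit_clock(X, y, sel.lambda_opt, opts)
        assert clock.n_coefficients <= 10

    def test_one_se_is_larger(self):
        X, y = _toy_regression(seed=2, n=80, p=50, noise=0.5)
        lam_min = select_lambda(X, y, FitOptions(n_folds=5, seed=0)).lambda_opt
        lam_1se = select_lambda(X, y, FitOptions(n_folds=5, seed=0, lambda_rule="one_se")).lambda_opt
        assert lam_1se >= lam_min

    def test_cv_curve_exposed(self):
        X, y = _toy_regression()
        sel = select_lambda(X, y, FitOptions(n_folds=5))
        assert len(sel.cv_curve) == len(sel.lambdas) == 100


class TestFitClock:
    def test_lambda_zero_equals_ols(self):
        X, y = _toy_regression(seed=1)
        clock = fit_clock(X, y, 0.0, FitOptions())
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert clock.intercept == pytest.approx(ols.params[0], abs=1e-6)
        beta = [clock.coefficients.get(f"x{i}", 0.0) for i in range(3)]
        assert np.allclose(beta, ols.params[1:], atol=1e-6)

    def test_huge_lambda_empty_model(self):
        X, y = _toy_regression(seed=2)
        clock = fit_clock(X, y, 1e6, FitOptions())
        assert clock.n_coefficients == 0
        assert clock.intercept == pytest.approx(y.mean())

    def test_nonfinite_rejected(self):
        X, y = _toy_regression()
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="non-finite"):
            fit_clock(X, y, 0.1, FitOptions())

    def test_objective_no_worse_than_zero_vector(self):
        X, y = _toy_regression(seed=4, n=60, p=30, noise=0.3)
        for lam in (0.001, 0.01, 0.1):
            opts = FitOptions(standardize=False)
            clock = fit_clock(X, y, lam, opts)
            beta = np.array([clock.coefficients.get(f"x{i}", 0.0) for i in range(30)])
            at_fit = elastic_net_objective(X, y, clock.intercept, beta, lam, opts.alpha)
            at_zero = elastic_net_objective(X, y, y.mean(), np.zeros(30), lam, opts.alpha)
            assert at_fit <= at_zero + 1e-12

    def test_lasso_support_recovery(self):
        # 10 true predictors among 500; LASSO at lambda_opt recovers >= 7.
        rng = np.random.default_rng(17)
        n, p, k = 100, 500, 10
        X = rng.uniform(0, 1, size=(n, p))
        true_idx = rng.choice(p, size=k, replace=False)
        beta = np.zeros(p)
        beta[true_idx] = rng.choice([-1, 1], k) * rng.uniform(1.0, 2.0, k)
        y = X @ beta + rng.normal(0, 0.5, n)
        opts = FitOptions(alpha=1.0, n_folds=5, seed=3)
        sel = select_lambda(X, y, opts)
        clock = fit_clock(X, y, sel.lambda_opt, opts)
        selected = {int(name[1:]) for name in clock.coefficients}
        assert len(selected & set(true_idx.tolist())) >= 7

    def test_provenance_recorded(self):
        X, y = _toy_regression()
        clock = fit_clock(X, y, 0.05, FitOptions(seed=9))
        for key in ("alpha", "lambda", "seed", "n_samples", "n_probes"):
            assert key in clock.provenance
        assert clock.provenance["lambda"] == 0.05


class TestImputeMissing:
    def test_no_missing_is_identity(self, small_cohort):
        out = impute_missing(small_cohort.betas)
        assert out is small_cohort.betas

    def test_mean_imputation(self):
        bm = make_betas([[0.2, np.nan, 0.4]])
        out = impute_missing(bm)
        assert out.values[0, 1] == pytest.approx(0.3)

    def test_all_missing_probe_rejected(self):
        bm = make_betas([[np.nan, np.nan]])
        with pytest.raises(ValidationError, match="no observed values"):
            impute_missing(bm)


class TestBuildClock:
    def test_training_r_high_on_synthetic(self):
        cohort = simulate_cohort(SimConfig(
            n_samples_per_species=34, n_probes=500, n_signal_probes=40, seed=21
        ))
        clock, report = build_clock(
            cohort.betas, cohort.sheet, cohort.species_table,
            TransformSpec("relative_age"), FitOptions(seed=2),
        )
        assert report["training_r"] >= 0.95
        assert clock.n_coefficients > 0

    def test_transform_recorded_in_report(self, small_cohort):
        for name in ("identity", "relative_age"):
            _, report = build_clock(
                small_cohort.betas, small_cohort.sheet, small_cohort.species_table,
                TransformSpec(name), FitOptions(n_folds=5, seed=0),
            )
            assert report["transform"] == name

    def test_single_collinear_probe(self):
        # One probe perfectly linear in age dominates at a small penalty.
        n = 30
        ages = np.linspace(1.0, 9.0, n)
        probe = 0.1 + 0.08 * ages
        rng = np.random.default_rng(0)
        other = rng.uniform(0.4, 0.6, size=(2, n))
        bm = make_betas(np.vstack([probe, other]), probes=["cg_sig", "cg_a", "cg_b"],
                        samples=[f"s{i}" for i in range(n)])
        sheet = make_sheet([f"s{i}" for i in range(n)], ages)
        opts = FitOptions(n_folds=5, seed=0)
        clock, report = build_clock(bm, sheet, None, TransformSpec("identity"), opts)
        assert "cg_sig" in clock.coefficients
        assert abs(clock.coefficients["cg_sig"]) > sum(
            abs(v) for k, v in clock.coefficients.items() if k != "cg_sig"
        )
        assert report["training_r"] >= 0.999

    def test_missing_ages_rejected(self):
        bm = make_betas(np.full((3, 4), 0.5), samples=["a", "b", "c", "d"])
        sheet = make_sheet(["a", "b", "c", "d"], [1.0, 2.0, np.nan, 4.0])
        with pytest.raises(ValidationError, match="missing age"):
            build_clock(bm, sheet, None, TransformSpec("identity"), FitOptions(n_folds=3))
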