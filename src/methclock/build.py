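"""Fitting new clocks by sparse penalized regression of transformed age on betas.

The solver minimizes the elastic-net objective

    (1/2n) * ||y - b0 - X b||^2 + lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2)

with ``alpha`` the L1/L2 mixing (1 = LASSO). The penalty strength ``lambda``
is chosen by internal k-fold cross-validation over a log-spaced path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import enet_path
from sklearn.model_selection import KFold

from .core import (
    BetaMatrix,
    ClockDefinition,
    MethclockError,
    SampleSheet,
    SpeciesTable,
    TransformSpec,
    ValidationError,
    inverse_transform_age,
    transform_age,
)

logger = logging.getLogger(__name__)

__all__ = ["FitOptions", "LambdaSelection", "select_lambda", "fit_clock", "build_clock"]

N_LAMBDAS = 100
LAMBDA_DECADES = 4  # path spans lambda_max down to lambda_max * 10**-4
IMPUTE_WARN_FRACTION = 0.2


@dataclass(frozen=True)
class FitOptions:
    """Penalty and cross-validation settings for clock fitting."""

    alpha: float = 0.5
    n_folds: int = 10
    lambda_rule: str = "min"  # or "one_se"
    seed: int = 0
    standardize: bool = True
    fold_by_species: bool = False
    tol: float = 1e-4
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_folds < 3:
            raise ValidationError(f"n_folds must be >= 3, got {self.n_folds}")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValidationError(f"lambda_rule must be 'min' or 'one_se', got {self.lambda_rule!r}")


@dataclass
class LambdaSelection:
    lambda_opt: float
    lambdas: np.ndarray
    mean_cv_error: np.ndarray
    se_cv_error: np.ndarray
    rule: str

    @property
    def cv_curve(self) -> dict[float, float]:
        return dict(zip(self.lambdas.tolist(), self.mean_cv_error.tolist()))


def _check_design(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-D, got shape {X.shape}")
    if y.shape != (X.shape[0],):
        raise ValidationError(f"y length {y.shape} does not match {X.shape[0]} rows of X")
    if not np.isfinite(X).all():
        raise ValidationError("X contains non-finite values; impute or filter upstream")
    if not np.isfinite(y).all():
        raise ValidationError("y contains non-finite values")
    return X, y


def _scales(X: np.ndarray, standardize: bool) -> np.ndarray:
    if not standardize:
        return np.ones(X.shape[1])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return sd


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, standardize: bool) -> np.ndarray:
    """Log-spaced path from lambda_max (smallest lambda zeroing every
    coefficient) down by ``LAMBDA_DECADES`` orders of magnitude."""
    n = X.shape[0]
    Xc = (X - X.mean(axis=0)) / _scales(X, standardize)
    yc = y - y.mean()
    # For alpha -> 0 lambda_max diverges; cap the divisor as glmnet does.
    denom = max(alpha, 1e-3)
    lambda_max = np.max(np.abs(Xc.T @ yc)) / (n * denom)
    if lambda_max <= 0:
        raise ValidationError("all predictors are orthogonal to y; cannot build a path")
    return np.geomspace(lambda_max, lambda_max * 10.0 ** (-LAMBDA_DECADES), N_LAMBDAS)


def select_lambda(X: np.ndarray, y: np.ndarray, opts: FitOptions,
                  groups: np.ndarray | None = None,
                  sample_keys: list[str] | None = None) -> LambdaSelection:
    """Pick the penalty by k-fold CV MSE over the lambda path.

    ``lambda_rule='min'`` takes the minimizer of the mean CV error;
    ``'one_se'`` the largest lambda whose mean error is within one standard
    error of that minimum. Reproducible for a fixed ``opts.seed``.
    ``groups`` (optional) folds whole groups together (e.g. by species).
    ``sample_keys`` (optional, e.g. sample ids) makes fold membership a
    function of the keys rather than of row order, so permuting the input
    rows does not change the selected lambda.
    """
    X, y = _check_design(X, y)
    n = X.shape[0]
    if np.ptp(y) == 0:
        raise ValidationError("response y is constant; cannot cross-validate a regression")
    if n < opts.n_folds:
        raise ValidationError(f"n={n} samples < n_folds={opts.n_folds}")

    lambdas = _lambda_path(X, y, opts.alpha, opts.standardize)
    folds = _make_folds(n, opts, groups, sample_keys)

    sq_errors = np.full((n, len(lambdas)), np.nan)
    for train_idx, test_idx in folds:
        Xtr, ytr = X[train_idx], y[train_idx]
        scale = _scales(Xtr, opts.standardize)
        x_mean = Xtr.mean(axis=0)
        y_mean = ytr.mean()
        Xs = (Xtr - x_mean) / scale
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # CV curves only need to rank lambdas; a loose tolerance is
            # enough and keeps the 100-point path fast.
            _, coefs, _ = enet_path(
                Xs, ytr - y_mean, l1_ratio=max(opts.alpha, 1e-12),
                alphas=lambdas, tol=1e-4, max_iter=2000,
            )
        Xte = (X[test_idx] - x_mean) / scale
        preds = Xte @ coefs + y_mean  # (n_test, n_lambdas)
        sq_errors[test_idx, :] = (preds - y[test_idx][:, None]) ** 2

    mean_err = sq_errors.mean(axis=0)
    # SE of the CV estimate from per-fold means, matching glmnet convention.
    fold_means = np.array([sq_errors[test_idx].mean(axis=0) for _, test_idx in folds])
    se = fold_means.std(axis=0, ddof=1) / np.sqrt(len(folds))

    i_min = int(np.argmin(mean_err))
    if opts.lambda_rule == "min":
        i_opt = i_min
    else:
        threshold = mean_err[i_min] + se[i_min]
        within = np.where(mean_err <= threshold)[0]
        i_opt = int(within.min())  # lambdas are decreasing: first index = largest lambda
    return LambdaSelection(
        lambda_opt=float(lambdas[i_opt]),
        lambdas=lambdas,
        mean_cv_error=mean_err,
        se_cv_error=se,
        rule=opts.lambda_rule,
    )


def _make_folds(n: int, opts: FitOptions, groups: np.ndarray | None,
                sample_keys: list[str] | None = None):
    if groups is not None and opts.fold_by_species:
        uniq = pd.unique(pd.Series(groups))
        if len(uniq) < 2:
            raise ValidationError("fold_by_species requires >= 2 species")
        folds = []
        for g in uniq:
            test_idx = np.where(np.asarray(groups) == g)[0]
            train_idx = np.where(np.asarray(groups) != g)[0]
            folds.append((train_idx, test_idx))
        return folds
    kf = KFold(n_splits=opts.n_folds, shuffle=True, random_state=opts.seed)
    if sample_keys is None:
        return list(kf.split(np.arange(n)))
    # Canonical order by key: fold membership depends on the keys, not on
    # the order in which rows happen to arrive.
    order = np.argsort(np.asarray(sample_keys, dtype=object), kind="stable")
    return [(order[tr], order[te]) for tr, te in kf.split(np.arange(n))]


def fit_clock(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    opts: FitOptions,
    transform: TransformSpec | None = None,
    name: str = "clock",
    probe_ids: list[str] | None = None,
) -> ClockDefinition:
    """Fit the elastic net at a fixed penalty and package the sparse result.

    ``lam=0`` is solved exactly by least squares (the unpenalized limit).
    Only non-zero coefficients are stored.
    """
    X, y = _check_design(X, y)
    n, p = X.shape
    if probe_ids is None:
        probe_ids = [f"x{i}" for i in range(p)]
    if len(probe_ids) != p:
        raise ValidationError(f"{len(probe_ids)} probe ids for {p} columns")
    if lam < 0:
        raise ValidationError(f"lambda must be >= 0, got {lam}")

    if lam == 0:
        design = np.column_stack([np.ones(n), X])
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept, beta = float(sol[0]), sol[1:]
    else:
        # Solve by coordinate descent warm-started along a decreasing lambda
        # path ending at the target (pathwise fits converge far faster than a
        # cold start at a small lambda, and the result is deterministic for
        # fixed inputs and options).
        scale = _scales(X, opts.standardize)
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xs = (X - x_mean) / scale
        yc = y - y_mean
        try:
            full_path = _lambda_path(X, y, opts.alpha, opts.standardize)
            warmup = full_path[full_path > lam]
        except ValidationError:
            warmup = np.array([])
        alphas = np.append(warmup, lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = enet_path(
                Xs, yc, l1_ratio=max(opts.alpha, 1e-12), alphas=alphas,
                tol=opts.tol, max_iter=opts.max_iter,
            )
        beta_std = coefs[:, -1]
        beta = beta_std / scale
        intercept = float(y_mean - x_mean @ beta)

    coefficients = {pid: float(b) for pid, b in zip(probe_ids, beta) if b != 0.0}
    provenance = {
        "alpha": opts.alpha,
        "lambda": float(lam),
        "seed": opts.seed,
        "n_samples": n,
        "n_probes": p,
        "standardize": opts.standardize,
    }
    clock = ClockDefinition(
        clock_name=name,
        intercept=intercept,
        coefficients=coefficients,
        transform=transform if transform is not None else TransformSpec(),
        provenance=provenance,
    )
    return clock


def impute_missing(betas: BetaMatrix) -> BetaMatrix:
    """Mean-impute missing betas per probe across samples.

    Probes missing in more than ``IMPUTE_WARN_FRACTION`` of samples trigger a
    warning — such probes are better removed upstream.
    """
    values = betas.values
    nan_mask = np.isnan(values)
    if not nan_mask.any():
        return betas
    frac = nan_mask.mean(axis=1)
    n_heavy = int((frac > IMPUTE_WARN_FRACTION).sum())
    if n_heavy:
        logger.warning(
            "imputing %d probe(s) missing in > %.0f%% of samples; consider removing them upstream",
            n_heavy, 100 * IMPUTE_WARN_FRACTION,
        )
    all_missing = nan_mask.all(axis=1)
    if all_missing.any():
        raise ValidationError(
            f"{int(all_missing.sum())} probe(s) have no observed values; remove them before fitting"
        )
    filled = values.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        probe_means = np.nanmean(values, axis=1)
    idx = np.where(nan_mask)
    filled[idx] = probe_means[idx[0]]
    return BetaMatrix(filled, betas.probe_ids, betas.sample_ids)


def transformed_ages(
    sheet: SampleSheet, species_table: SpeciesTable | None, transform: TransformSpec
) -> np.ndarray:
    out = np.empty(len(sheet))
    for i, (_, row) in enumerate(sheet.frame.iterrows()):
        species = species_table.get(row["species"]) if transform.needs_species else None
        out[i] = transform_age(row["age"], transform, species)
    return out


def build_clock(
    betas: BetaMatrix,
    sheet: SampleSheet,
    species_table: SpeciesTable | None = None,
    transform: TransformSpec | None = None,
    opts: FitOptions | None = None,
    name: str = "clock",
) -> tuple[ClockDefinition, dict]:
    """End-to-end clock construction: transform ages, pick lambda, fit.

    Probe pre-filtering is NOT applied implicitly; pass an already filtered
    matrix. Returns ``(clock, training_report)`` where the report carries
    in-sample fit quality on the years scale and the lambda-path summary.
    """
    transform = transform if transform is not None else TransformSpec()
    opts = opts if opts is not None else FitOptions()
    sheet = sheet.reindex(betas.sample_ids)
    sheet.require_complete_ages()

    betas = impute_missing(betas)
    y = transformed_ages(sheet, species_table, transform)
    X = betas.values.T  # samples x probes

    groups = np.array(sheet.species) if opts.fold_by_species else None
    selection = select_lambda(X, y, opts, groups=groups, sample_keys=sheet.sample_ids)
    clock = fit_clock(X, y, selection.lambda_opt, opts, transform, name, betas.probe_ids)
    clock.provenance["lambda_rule"] = opts.lambda_rule
    clock.provenance["transform"] = transform.name

    # In-sample diagnostics on the interpretable (years) scale.
    fitted_lp = clock.intercept + X @ np.array(
        [clock.coefficients.get(p, 0.0) for p in betas.probe_ids]
    )
    fitted_age = np.array([
        inverse_transform_age(
            lp, transform,
            species_table.get(sp) if transform.needs_species else None,
            clamp=True,
        )
        for lp, sp in zip(fitted_lp, sheet.species)
    ])
    true_age = sheet.ages
    report = {
        "n_samples": len(sheet),
        "n_probes": betas.n_probes,
        "n_selected": clock.n_coefficients,
        "transform": transform.name,
        "lambda_opt": selection.lambda_opt,
        "lambda_rule": opts.lambda_rule,
        "lambda_path": {
            "max": float(selection.lambdas[0]),
            "min": float(selection.lambdas[-1]),
            "n": len(selection.lambdas),
        },
        "training_r": float(np.corrcoef(fitted_age, true_age)[0, 1]) if np.ptp(true_age) else float("nan"),
        "training_mae_years": float(np.mean(np.abs(fitted_age - true_age))),
    }
    return clock, report
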