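"""Leave-One-Out and Leave-One-Species-Out evaluation of clocks.

Both schemes use a computational shortcut: the penalty ``lambda`` is chosen
once by internal cross-validation on the full dataset and then reused for
every fold, instead of re-tuning inside each fold (fold-level optima are
typically nearly identical). A ``per_fold_lambda`` escape hatch re-tunes per
fold when that assumption is in doubt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .build import (
    FitOptions,
    fit_clock,
    impute_missing,
    select_lambda,
    transformed_ages,
)
from .core import (
    BetaMatrix,
    ClockDefinition,
    SampleSheet,
    SpeciesTable,
    TransformSpec,
    ValidationError,
    inverse_transform_age,
)

logger = logging.getLogger(__name__)

__all__ = ["CVResult", "loo_estimate", "loso_estimate", "cv_metrics"]


@dataclass
class CVResult:
    """Predictions, archived per-fold clocks and summary metrics."""

    predictions: pd.DataFrame  # sample_id, fold_id, linear_predictor, dnam_age, true_age
    fold_clocks: list[ClockDefinition]
    metrics: dict
    options: dict = field(default_factory=dict)
    per_species_metrics: dict | None = None


def cv_metrics(pred_ages, true_ages) -> dict:
    """Pearson r, mean and median absolute error (years) of predictions."""
    pred = np.asarray(pred_ages, dtype=float)
    true = np.asarray(true_ages, dtype=float)
    if pred.shape != true.shape:
        raise ValidationError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size < 2:
        raise ValidationError("need at least 2 predictions for metrics")
    abs_err = np.abs(pred - true)
    if np.ptp(true) == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(pred, true)[0, 1])
    return {
        "pearson_r": r,
        "mae_years": float(abs_err.mean()),
        "median_ae_years": float(np.median(abs_err)),
    }


def _prepare(betas, sheet, species_table, transform, opts):
    sheet = sheet.reindex(betas.sample_ids)
    sheet.require_complete_ages()
    betas = impute_missing(betas)
    y = transformed_ages(sheet, species_table, transform)
    X = betas.values.T
    return betas, sheet, X, y


def _fit_fold(X, y, train_idx, lam, opts, transform, name, probe_ids):
    y_train = y[train_idx]
    if np.ptp(y_train) == 0:
        raise ValidationError(f"fold {name!r}: training ages are constant")
    return fit_clock(X[train_idx], y_train, lam, opts, transform, name, probe_ids)


def _predict_fold(clock, X, test_idx, transform, sheet, species_table, probe_ids):
    coef = np.array([clock.coefficients.get(p, 0.0) for p in probe_ids])
    rows = []
    for i in test_idx:
        lp = clock.intercept + float(X[i] @ coef)
        sp = sheet.species[i]
        species = species_table.get(sp) if transform.needs_species else None
        rows.append((sheet.sample_ids[i], lp,
                     inverse_transform_age(lp, transform, species, clamp=True)))
    return rows


def _run_folds(betas, sheet, species_table, transform, opts, folds, fold_ids,
               per_fold_lambda, scheme):
    X = betas.values.T
    y = transformed_ages(sheet, species_table, transform)
    probe_ids = betas.probe_ids

    if per_fold_lambda:
        lam_shared = None
    else:
        groups = np.array(sheet.species) if opts.fold_by_species else None
        lam_shared = select_lambda(
            X, y, opts, groups=groups, sample_keys=sheet.sample_ids
        ).lambda_opt
        logger.info("%s: single lambda %.6g selected on the full dataset", scheme, lam_shared)

    fold_clocks: list[ClockDefinition] = []
    pred_rows = []
    for fold_id, (train_idx, test_idx) in zip(fold_ids, folds):
        lam = lam_shared
        if per_fold_lambda:
            lam = select_lambda(X[train_idx], y[train_idx], opts).lambda_opt
        clock = _fit_fold(X, y, train_idx, lam, opts, transform,
                          f"{scheme}_fold_{fold_id}", probe_ids)
        fold_clocks.append(clock)
        for sample_id, lp, age in _predict_fold(
            clock, X, test_idx, transform, sheet, species_table, probe_ids
        ):
            pred_rows.append((sample_id, fold_id, lp, age))

    preds = pd.DataFrame(pred_rows, columns=["sample_id", "fold_id", "linear_predictor", "dnam_age"])
    truth = sheet.frame.set_index("sample_id")["age"]
    preds["true_age"] = preds["sample_id"].map(truth)
    preds = preds.set_index("sample_id").loc[betas.sample_ids].reset_index()
    return preds, fold_clocks


def loo_estimate(
    betas: BetaMatrix,
    sheet: SampleSheet,
    species_table: SpeciesTable | None = None,
    transform: TransformSpec | None = None,
    opts: FitOptions | None = None,
    per_fold_lambda: bool = False,
) -> CVResult:
    """Leave-one-out: refit on all-but-one sample, predict the one left out.

    Each fold's coefficient table is archived in ``fold_clocks`` (one clock
    per sample, in sample order). Metrics are reported on the years scale.
    """
    transform = transform if transform is not None else TransformSpec()
    opts = opts if opts is not None else FitOptions()
    betas, sheet, X, y = _prepare(betas, sheet, species_table, transform, opts)
    n = len(sheet)
    if n < opts.n_folds + 1:
        raise ValidationError(f"LOO needs n >= n_folds + 1 ({opts.n_folds + 1}), got {n}")

    if np.ptp(y) == 0:
        # Degenerate cohort: every age identical. No penalty can be tuned;
        # each fold reduces to the intercept-only model predicting the
        # common (transformed) age.
        logger.warning("LOO: all ages identical; returning intercept-only fold clocks")
        common = float(y[0])
        rows, clocks = [], []
        for i, sid in enumerate(sheet.sample_ids):
            clock = ClockDefinition(
                clock_name=f"loo_fold_{i}", intercept=common, coefficients={},
                transform=transform, provenance={"lambda": float("inf"), "degenerate": True},
            )
            clocks.append(clock)
            species = species_table.get(sheet.species[i]) if transform.needs_species else None
            rows.append((sid, i, common, inverse_transform_age(common, transform, species)))
        preds = pd.DataFrame(rows, columns=["sample_id", "fold_id", "linear_predictor", "dnam_age"])
        preds["true_age"] = sheet.ages
        metrics = cv_metrics(preds["dnam_age"], preds["true_age"])
        return CVResult(predictions=preds, fold_clocks=clocks, metrics=metrics,
                        options={"mode": "loo", "degenerate": True, **_opts_echo(opts)})

    all_idx = np.arange(n)
    folds = [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    preds, fold_clocks = _run_folds(
        betas, sheet, species_table, transform, opts, folds,
        fold_ids=list(range(n)), per_fold_lambda=per_fold_lambda, scheme="loo",
    )
    metrics = cv_metrics(preds["dnam_age"], preds["true_age"])
    metrics.update(_transformed_scale_metrics(preds, y, sheet))
    return CVResult(
        predictions=preds,
        fold_clocks=fold_clocks,
        metrics=metrics,
        options={"mode": "loo", "per_fold_lambda": per_fold_lambda, **_opts_echo(opts)},
    )


def loso_estimate(
    betas: BetaMatrix,
    sheet: SampleSheet,
    species_table: SpeciesTable | None = None,
    transform: TransformSpec | None = None,
    opts: FitOptions | None = None,
    per_fold_lambda: bool = False,
) -> CVResult:
    """Leave-one-species-out: one fold per species, the whole species held out.

    The held-out species contributes zero training rows to its fold — this is
    asserted on every run, not only under test. Per-species metrics are
    reported alongside the pooled ones.
    """
    transform = transform if transform is not None else TransformSpec()
    opts = opts if opts is not None else FitOptions()

    if transform.needs_species and species_table is not None:
        known = {s for s in sheet.species if s in species_table}
        dropped = [sid for sid, sp in zip(sheet.sample_ids, sheet.species) if sp not in known]
        if dropped:
            logger.warning(
                "LOSO: excluding %d sample(s) whose species lacks parameters: %s",
                len(dropped), dropped[:10],
            )
            keep = [s for s in sheet.sample_ids if s not in set(dropped)]
            betas = betas.select_samples(keep)
    betas, sheet, X, y = _prepare(betas, sheet, species_table, transform, opts)

    species = np.array(sheet.species)
    uniq = list(pd.unique(species))
    if len(uniq) < 2:
        raise ValidationError("LOSO requires at least 2 species")

    folds = []
    for sp in uniq:
        test_idx = np.where(species == sp)[0]
        train_idx = np.where(species != sp)[0]
        # Hard leakage assertion: held-out species never in training.
        assert not set(np.array(sheet.species)[train_idx]) & {sp}, (
            f"LOSO leakage: species {sp!r} present in its own training fold"
        )
        folds.append((train_idx, test_idx))

    preds, fold_clocks = _run_folds(
        betas, sheet, species_table, transform, opts, folds,
        fold_ids=uniq, per_fold_lambda=per_fold_lambda, scheme="loso",
    )
    metrics = cv_metrics(preds["dnam_age"], preds["true_age"])
    metrics.update(_transformed_scale_metrics(preds, y, sheet))
    per_species = {}
    for sp in uniq:
        sub = preds[preds["fold_id"] == sp]
        if len(sub) >= 2:
            per_species[sp] = cv_metrics(sub["dnam_age"], sub["true_age"])
    return CVResult(
        predictions=preds,
        fold_clocks=fold_clocks,
        metrics=metrics,
        options={"mode": "loso", "per_fold_lambda": per_fold_lambda, **_opts_echo(opts)},
        per_species_metrics=per_species,
    )


def _opts_echo(opts: FitOptions) -> dict:
    return {
        "alpha": opts.alpha,
        "n_folds": opts.n_folds,
        "lambda_rule": opts.lambda_rule,
        "seed": opts.seed,
        "standardize": opts.standardize,
    }


def _transformed_scale_metrics(preds: pd.DataFrame, y: np.ndarray, sheet: SampleSheet) -> dict:
    lp = preds.set_index("sample_id").loc[sheet.sample_ids, "linear_predictor"].to_numpy()
    if np.ptp(y) == 0:
        return {}
    return {
        "pearson_r_transformed": float(np.corrcoef(lp, y)[0, 1]),
        "mae_transformed": float(np.mean(np.abs(lp - y))),
    }
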