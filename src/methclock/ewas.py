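"""Epigenome-wide association of methylation with age (or another outcome).

Each probe is correlated with the outcome across samples; inference uses the
Fisher z-transform, z = atanh(r) * sqrt(n - 3), against a standard normal.
A fixed-weight Stouffer combination provides meta-analysis across strata
(e.g. species or tissues).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["EWASResult", "ewas_correlate", "meta_ewas", "biweight_midcorrelation"]


@dataclass
class EWASResult:
    """Per-probe association statistics against one outcome."""

    table: pd.DataFrame  # index probe_id; columns r, n_used, z, p, q
    outcome: str = "age"
    stratum: str = "all"
    method: str = "pearson"


def _attach_inference(table: pd.DataFrame, adjust: str = "bh") -> pd.DataFrame:
    ok = table["z"].notna()
    p = np.full(len(table), np.nan)
    p[ok.to_numpy()] = 2.0 * stats.norm.sf(np.abs(table.loc[ok, "z"].to_numpy()))
    table["p"] = p
    q = np.full(len(table), np.nan)
    if ok.any():
        if adjust == "bh":
            q[ok.to_numpy()] = multipletests(p[ok.to_numpy()], method="fdr_bh")[1]
        elif adjust == "bonferroni":
            q[ok.to_numpy()] = np.minimum(p[ok.to_numpy()] * ok.sum(), 1.0)
        else:
            raise ValidationError(f"unknown adjustment {adjust!r}")
    table["q"] = q
    return table


def biweight_midcorrelation(x: np.ndarray, y: np.ndarray, c: float = 9.0) -> float:
    """Robust correlation via biweight midcovariance (median/MAD weighting)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def _weights(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return np.full_like(v, np.nan)
        u = (v - med) / (c * mad)
        w = (1 - u**2) ** 2
        w[np.abs(u) >= 1] = 0.0
        return (v - med) * w

    a, b = _weights(x), _weights(y)
    if np.isnan(a).any() or np.isnan(b).any():
        return float("nan")
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(a * b) / denom)


def ewas_correlate(
    betas: BetaMatrix,
    outcome,
    min_n: int = 10,
    outcome_name: str = "age",
    stratum: str = "all",
    method: str = "pearson",
    adjust: str = "bh",
) -> EWASResult:
    """Correlate every probe with the outcome across samples.

    Probes are evaluated pairwise-complete; a probe with fewer than ``min_n``
    usable samples is reported as NA. BH q-values are computed over the
    non-NA probes.
    """
    outcome = np.asarray(outcome, dtype=float)
    if outcome.shape != (betas.n_samples,):
        raise ValidationError(
            f"outcome length {outcome.shape} does not match {betas.n_samples} samples"
        )
    usable_outcome = outcome[~np.isnan(outcome)]
    if usable_outcome.size < 3 or np.ptp(usable_outcome) == 0:
        raise ValidationError("outcome is constant or nearly empty; correlation undefined")
    if method not in ("pearson", "bicor"):
        raise ValidationError(f"method must be 'pearson' or 'bicor', got {method!r}")

    values = betas.values
    rs = np.full(betas.n_probes, np.nan)
    ns = np.zeros(betas.n_probes, dtype=int)

    complete = ~(np.isnan(values).any() or np.isnan(outcome).any())
    if complete and method == "pearson":
        # Vectorized Pearson over all probes at once.
        yc = outcome - outcome.mean()
        xc = values - values.mean(axis=1, keepdims=True)
        num = xc @ yc
        denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rs = np.where(denom > 0, num / denom, np.nan)
        ns[:] = betas.n_samples
    else:
        for i in range(betas.n_probes):
            x = values[i]
            mask = ~(np.isnan(x) | np.isnan(outcome))
            n = int(mask.sum())
            ns[i] = n
            if n < max(min_n, 3) or np.ptp(x[mask]) == 0 or np.ptp(outcome[mask]) == 0:
                continue
            if method == "pearson":
                rs[i] = stats.pearsonr(x[mask], outcome[mask])[0]
            else:
                rs[i] = biweight_midcorrelation(x[mask], outcome[mask])
    rs = np.clip(rs, -1.0, 1.0)
    low_n = ns < min_n
    rs[low_n] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.arctanh(rs) * np.sqrt(np.maximum(ns - 3, 0))
    table = pd.DataFrame(
        {"r": rs, "n_used": ns, "z": z}, index=pd.Index(betas.probe_ids, name="probe_id")
    )
    table = _attach_inference(table, adjust=adjust)
    n_na = int(table["r"].isna().sum())
    if n_na:
        logger.info("EWAS: %d probe(s) reported NA (insufficient n or zero variance)", n_na)
    return EWASResult(table=table, outcome=outcome_name, stratum=stratum, method=method)


def meta_ewas(
    results: list[EWASResult],
    weights: str = "sqrt_n",
    adjust: str = "bh",
) -> EWASResult:
    """Stouffer meta-analysis across strata.

    z_meta = sum(w_s * z_s) / sqrt(sum(w_s^2)) with w_s = sqrt(n_s) or 1.
    Probes are aligned by id over the union; all-NA rows are dropped with a
    logged count. p and BH q are recomputed on z_meta.
    """
    if len(results) < 2:
        raise ValidationError("meta-analysis needs at least 2 strata")
    if weights not in ("sqrt_n", "equal"):
        raise ValidationError(f"weights must be 'sqrt_n' or 'equal', got {weights!r}")

    all_probes = pd.Index([], name="probe_id")
    for res in results:
        all_probes = all_probes.union(res.table.index)

    z_mat = np.full((len(all_probes), len(results)), np.nan)
    w_mat = np.full_like(z_mat, np.nan)
    for s, res in enumerate(results):
        sub = res.table.reindex(all_probes)
        z_mat[:, s] = sub["z"].to_numpy()
        if weights == "sqrt_n":
            w_mat[:, s] = np.sqrt(sub["n_used"].to_numpy(dtype=float))
        else:
            w_mat[:, s] = 1.0

    valid = ~np.isnan(z_mat)
    n_strata = valid.sum(axis=1)
    all_na = n_strata == 0
    if all_na.any():
        logger.info("meta-EWAS: dropping %d probe(s) with no usable stratum", int(all_na.sum()))

    w = np.where(valid, w_mat, 0.0)
    z = np.where(valid, z_mat, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_meta = (w * z).sum(axis=1) / np.sqrt((w**2).sum(axis=1))
    z_meta[all_na] = np.nan

    table = pd.DataFrame(
        {
            "z": z_meta,
            "n_used": _total_n(results, all_probes, valid),
            "n_strata": n_strata,
        },
        index=all_probes,
    )
    table = table[~all_na]
    table["r"] = np.nan  # no single pooled correlation; z is the meta statistic
    table = _attach_inference(table, adjust=adjust)
    outcome = results[0].outcome
    return EWASResult(table=table, outcome=outcome, stratum="meta", method="stouffer")


def _total_n(results: list[EWASResult], probes: pd.Index, valid: np.ndarray) -> np.ndarray:
    n = np.zeros((len(probes), len(results)))
    for s, res in enumerate(results):
        n[:, s] = res.table["n_used"].reindex(probes).fillna(0).to_numpy()
    return (n * valid).sum(axis=1).astype(int)
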