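"""Pre-filtering of CpG probes before clock training.

Three per-probe filters: genome-mappability (keep only probes whose sequence
maps to the target genome), middle filter (drop probes whose mean beta sits
near 0.5 — the technical artifact peak of probes that fail to align), and
detection-p filter (drop probes with too many failed detection calls).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeSelection",
    "middle_filter",
    "detection_p_filter",
    "mappability_filter",
    "bimodality_report",
    "DEFAULT_MIDDLE_WINDOW",
]

# "near 0.5" window; wide enough to catch the artifact peak, narrow enough to
# spare genuinely intermediate methylation. Configurable in every entry point.
DEFAULT_MIDDLE_WINDOW = (0.3, 0.7)


@dataclass
class ProbeSelection:
    """Partition of the input probes into kept and removed(+reason)."""

    kept: list[str]
    removed: dict[str, str]
    filter_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.kept) & set(self.removed)
        if overlap:
            raise ValidationError(f"probes both kept and removed: {sorted(overlap)[:10]}")

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def removed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"probe_id": list(self.removed), "reason": list(self.removed.values())}
        )


def probe_means(betas: BetaMatrix) -> np.ndarray:
    """Per-probe mean over non-missing samples (NaN if all missing)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(betas.values, axis=1)


def middle_filter(
    betas: BetaMatrix,
    lower: float = DEFAULT_MIDDLE_WINDOW[0],
    upper: float = DEFAULT_MIDDLE_WINDOW[1],
) -> ProbeSelection:
    """Remove probes whose mean beta lies in [lower, upper] (inclusive).

    Probes with no observed values are removed with reason ``all_missing``.
    """
    # lower == upper is allowed: it removes only probes whose mean hits the
    # point exactly (the window is inclusive on both ends).
    if not (0.0 <= lower <= upper <= 1.0):
        raise ValidationError(f"invalid middle window [{lower}, {upper}]")
    means = probe_means(betas)
    kept: list[str] = []
    removed: dict[str, str] = {}
    for probe, mean in zip(betas.probe_ids, means):
        if np.isnan(mean):
            removed[probe] = "all_missing"
        elif lower <= mean <= upper:
            removed[probe] = f"middle_mean={mean:.6g}"
        else:
            kept.append(probe)
    return ProbeSelection(kept, removed, {"filter": "middle", "lower": lower, "upper": upper})


def detection_p_filter(
    pvals: pd.DataFrame,
    p_threshold: float = 0.05,
    max_fail_fraction: float = 0.0,
    betas: BetaMatrix | None = None,
) -> ProbeSelection:
    """Remove probes whose fraction of failed detection calls is too high.

    A sample "fails" a probe when its detection p-value exceeds
    ``p_threshold``; the probe is removed when the failing fraction exceeds
    ``max_fail_fraction``. The defaults (0.05, 0) remove a probe on any
    single failure — the strictest reading of "discard probes with detection
    p-values exceeding 0.05". NaN p-values are ignored.
    """
    if not (0.0 <= p_threshold <= 1.0):
        raise ValidationError(f"p_threshold must be in [0, 1], got {p_threshold}")
    if not (0.0 <= max_fail_fraction <= 1.0):
        raise ValidationError(f"max_fail_fraction must be in [0, 1], got {max_fail_fraction}")
    values = pvals.to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValidationError("detection p-values must lie in [0, 1]")
    if betas is not None:
        if list(pvals.index) != list(betas.probe_ids) or list(pvals.columns) != list(betas.sample_ids):
            raise ValidationError("detection p-value matrix does not align with the beta matrix")
    n_obs = (~np.isnan(values)).sum(axis=1)
    n_fail = np.nansum(values > p_threshold, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fail_frac = np.where(n_obs > 0, n_fail / np.maximum(n_obs, 1), 0.0)
    kept: list[str] = []
    removed: dict[str, str] = {}
    for probe, frac in zip(pvals.index.astype(str), fail_frac):
        if frac > max_fail_fraction:
            removed[probe] = f"detection_fail_fraction={frac:.6g}"
        else:
            kept.append(probe)
    return ProbeSelection(
        kept, removed,
        {"filter": "detection_p", "p_threshold": p_threshold, "max_fail_fraction": max_fail_fraction},
    )


def mappability_filter(probes: list[str], annotation: set[str]) -> ProbeSelection:
    """Keep only probes whose id appears in the mappability annotation for
    the target species, preserving input order."""
    annotation = set(annotation)
    if not annotation:
        logger.warning("mappability annotation is EMPTY: every probe will be removed")
    kept = [p for p in probes if p in annotation]
    removed = {p: "unmappable" for p in probes if p not in annotation}
    if not kept:
        logger.warning("mappability filter removed all %d probes", len(probes))
    return ProbeSelection(kept, removed, {"filter": "mappability", "n_annotation": len(annotation)})


def bimodality_report(
    betas: BetaMatrix,
    bins: int = 20,
    window: tuple[float, float] = DEFAULT_MIDDLE_WINDOW,
) -> dict:
    """Histogram of probe means plus the fraction in the middle window.

    Beta values are normally bimodal (peaks near 0 and 1); a third peak near
    0.5 is the diagnostic for probes that fail to align to the target genome.
    """
    if bins < 3:
        raise ValidationError(f"bins must be >= 3, got {bins}")
    means = probe_means(betas)
    means = means[~np.isnan(means)]
    counts, edges = np.histogram(means, bins=bins, range=(0.0, 1.0))
    lo, hi = window
    middle_fraction = float(((means >= lo) & (means <= hi)).mean()) if means.size else 0.0
    return {
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
        "middle_fraction": middle_fraction,
        "window": list(window),
        "n_probes": int(means.size),
    }
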