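"""Seeded generator of synthetic multi-species methylation cohorts.

Structure mirrors what the rest of the toolkit assumes: a bimodal baseline
(probe means near 0 and 1), an optional "artifact" component of probes with
mean ~0.5 (the trimodal failure mode of probes that do not align to the
target genome), and a subset of signal probes whose beta values are linear
in transformed age — placing clock recovery exactly within model class,
which is the right fixture for testing the estimator, not biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    SampleSheet,
    SpeciesCharacteristics,
    SpeciesTable,
    TransformSpec,
    ValidationError,
    transform_age,
)

logger = logging.getLogger(__name__)

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "corrupt_sample", "DEFAULT_SPECIES"]

# Default acceptance cohort: 3 species spanning a 6x lifespan range.
DEFAULT_SPECIES = (
    SpeciesCharacteristics("species_a", max_lifespan=10.0, gestation=0.06, sexual_maturity=1.0),
    SpeciesCharacteristics("species_b", max_lifespan=25.0, gestation=0.30, sexual_maturity=3.0),
    SpeciesCharacteristics("species_c", max_lifespan=60.0, gestation=0.75, sexual_maturity=8.0),
)

CLIP_WARN_FRACTION = 0.05


@dataclass
class SimConfig:
    """Knobs of the cohort generator; all randomness flows from ``seed``."""

    n_samples_per_species: int = 50
    species: tuple[SpeciesCharacteristics, ...] = DEFAULT_SPECIES
    n_probes: int = 2000
    n_signal_probes: int = 100
    slope_range: tuple[float, float] = (0.25, 0.5)  # |slope| of beta per unit F(age)
    positive_fraction: float = 0.5  # share of signal probes with positive slope
    artifact_fraction: float = 0.1  # probes forced to mean ~0.5 (Bernoulli per probe)
    noise_sd: float = 0.03
    missing_rate: float = 0.0
    transform: TransformSpec = field(default_factory=lambda: TransformSpec("relative_age"))
    age_span_fraction: float = 0.9  # ages drawn uniform on (0, fraction * L)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_signal_probes > self.n_probes:
            raise ValidationError("n_signal_probes must be <= n_probes")
        for name in ("artifact_fraction", "missing_rate", "positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for sp in self.species:
            if sp.max_lifespan <= 0:
                raise ValidationError(f"degenerate species {sp.species!r}: L <= 0")


@dataclass
class SimulatedCohort:
    betas: BetaMatrix
    sheet: SampleSheet
    species_table: SpeciesTable
    truth: pd.DataFrame  # probe_id, role, slope
    clip_fraction: float

    @property
    def signal_probe_ids(self) -> list[str]:
        return self.truth.loc[self.truth["role"] == "signal", "probe_id"].tolist()


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a seeded multi-species cohort.

    Per species, ages are uniform on (0, age_span_fraction * L). Signal
    probes follow beta = intercept + slope * F(age) + N(0, noise_sd), with
    the intercept placed so the noiseless trajectory stays inside [0.05,
    0.95] (no clipping of the signal itself). Artifact probes are assigned
    per-probe Bernoulli(artifact_fraction) with mean ~0.5, low variance and
    no age signal. Output is bit-for-bit reproducible per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    species_table = SpeciesTable(cfg.species)

    # --- samples -----------------------------------------------------------
    sample_ids, ages, species_col = [], [], []
    for sp in cfg.species:
        for i in range(cfg.n_samples_per_species):
            sample_ids.append(f"{sp.species}_s{i:03d}")
            ages.append(rng.uniform(0.0, cfg.age_span_fraction * sp.max_lifespan))
            species_col.append(sp.species)
    n = len(sample_ids)
    sheet = SampleSheet(pd.DataFrame(
        {"sample_id": sample_ids, "age": ages, "species": species_col, "tissue": "blood"}
    ))
    f_age = np.array([
        transform_age(age, cfg.transform, species_table.get(sp))
        for age, sp in zip(ages, species_col)
    ])

    # --- probe roles -------------------------------------------------------
    probe_ids = [f"cg{i:05d}" for i in range(cfg.n_probes)]
    artifact_mask = rng.random(cfg.n_probes) < cfg.artifact_fraction
    non_artifact = np.where(~artifact_mask)[0]
    if len(non_artifact) < cfg.n_signal_probes:
        raise ValidationError("not enough non-artifact probes for the requested signal probes")
    signal_idx = rng.choice(non_artifact, size=cfg.n_signal_probes, replace=False)
    signal_mask = np.zeros(cfg.n_probes, dtype=bool)
    signal_mask[signal_idx] = True

    values = np.empty((cfg.n_probes, n))
    roles = np.where(artifact_mask, "artifact", "null")
    roles[signal_mask] = "signal"
    slopes = np.zeros(cfg.n_probes)

    f_lo, f_hi = float(f_age.min()), float(f_age.max())

    # Baselines: tight bimodal mixture near 0.05 / 0.95 for null probes.
    n_null = int((~artifact_mask & ~signal_mask).sum())
    low_peak = rng.random(n_null) < 0.5
    null_means = np.where(
        low_peak,
        rng.beta(10, 90, size=n_null),  # mean ~0.10, sd ~0.03
        rng.beta(90, 10, size=n_null),  # mean ~0.90
    )
    null_rows = np.where(~artifact_mask & ~signal_mask)[0]
    values[null_rows, :] = null_means[:, None]

    # Artifact probes: mean ~0.5, low variance, no age signal.
    art_rows = np.where(artifact_mask)[0]
    art_means = rng.normal(0.5, 0.02, size=len(art_rows))
    values[art_rows, :] = art_means[:, None]

    # Signal probes: linear in F(age); intercept chosen so the noiseless
    # trajectory spans [0.05, 0.95] without clipping.
    for row in signal_idx:
        sign = 1.0 if rng.random() < cfg.positive_fraction else -1.0
        mag = rng.uniform(*cfg.slope_range)
        slope = sign * mag
        span = mag * (f_hi - f_lo)
        if span > 0.9:
            raise ValidationError(
                f"signal slope {slope:.3g} spans {span:.3g} > 0.9 on the beta "
                f"scale; reduce slope_range for this transform"
            )
        if sign > 0:
            b0 = rng.uniform(0.05, 0.95 - span) - slope * f_lo
        else:
            b0 = rng.uniform(0.05 + span, 0.95) + mag * f_lo
        slopes[row] = slope
        values[row, :] = b0 + slope * f_age

    values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    clipped = (values < 0.0) | (values > 1.0)
    clip_fraction = float(clipped.mean())
    values = np.clip(values, 0.0, 1.0)
    if clip_fraction > CLIP_WARN_FRACTION:
        logger.warning("clip fraction %.3f exceeds %.2f", clip_fraction, CLIP_WARN_FRACTION)

    if cfg.missing_rate > 0:
        miss = rng.random(values.shape) < cfg.missing_rate
        values[miss] = np.nan

    truth = pd.DataFrame({"probe_id": probe_ids, "role": roles, "slope": slopes})
    betas = BetaMatrix(values, probe_ids, sample_ids)
    return SimulatedCohort(
        betas=betas, sheet=sheet, species_table=species_table,
        truth=truth, clip_fraction=clip_fraction,
    )


def corrupt_sample(betas: BetaMatrix, sample_id: str, seed: int = 0) -> BetaMatrix:
    """Return a copy with one sample's values permuted across probes.

    The permutation preserves the marginal distribution of that array but
    destroys its correlation with every other array — a clean positive
    control for outlier flagging.
    """
    if sample_id not in betas.sample_ids:
        raise ValidationError(f"unknown sample {sample_id!r}")
    rng = np.random.default_rng(seed)
    values = betas.values.copy()
    j = betas.sample_ids.index(sample_id)
    values[:, j] = rng.permutation(values[:, j])
    return BetaMatrix(values, betas.probe_ids, betas.sample_ids)
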