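"""Core clock model: domain types, age transformations, and DNAm-age prediction.

An epigenetic clock is a sparse linear model on methylation beta values,

    F(age) = intercept + sum_p coef_p * beta_p,

where ``F`` is an invertible, strictly increasing transformation of
chronological age that may depend on species life-history parameters
(maximum lifespan ``L``, gestation time ``g``, age of sexual maturity ``m``).
Predicted DNAm age is obtained by applying the inverse transform to the
linear predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaMatrix",
    "SampleSheet",
    "SpeciesCharacteristics",
    "SpeciesTable",
    "TransformSpec",
    "ClockDefinition",
    "MethclockError",
    "ValidationError",
    "TransformError",
    "transform_age",
    "inverse_transform_age",
    "linear_predictor",
    "predict_age",
    "TRANSFORM_NAMES",
    "register_transform",
]


class MethclockError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MethclockError):
    """Malformed or inconsistent input data."""


class TransformError(MethclockError):
    """Age outside a transform's domain, value outside its image, or an
    unknown/underspecified transform."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class BetaMatrix:
    """Probes x samples matrix of methylation fractions in [0, 1].

    Missing values are represented as NaN. Probe and sample identifiers are
    unique, ordered strings.
    """

    def __init__(self, values, probe_ids: Iterable[str], sample_ids: Iterable[str]):
        probe_ids = [str(p) for p in probe_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"beta matrix must be 2-D, got shape {values.shape}")
        if values.shape != (len(probe_ids), len(sample_ids)):
            raise ValidationError(
                f"beta matrix shape {values.shape} does not match "
                f"{len(probe_ids)} probes x {len(sample_ids)} samples"
            )
        if len(set(probe_ids)) != len(probe_ids):
            dupes = _duplicates(probe_ids)
            raise ValidationError(f"duplicate probe ids: {dupes[:10]}")
        if len(set(sample_ids)) != len(sample_ids):
            dupes = _duplicates(sample_ids)
            raise ValidationError(f"duplicate sample ids: {dupes[:10]}")
        bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 1)))
        if bad.size:
            offenders = [
                f"(probe={probe_ids[i]}, sample={sample_ids[j]}, value={values[i, j]!r})"
                for i, j in bad[:10]
            ]
            raise ValidationError(
                f"{len(bad)} beta value(s) outside [0, 1]; first offenders: "
                + "; ".join(offenders)
            )
        self.values = values
        self.probe_ids = probe_ids
        self.sample_ids = sample_ids
        self._probe_index = {p: i for i, p in enumerate(probe_ids)}
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        """Build from a probes-in-rows, samples-in-columns DataFrame."""
        return cls(frame.to_numpy(dtype=float), frame.index, frame.columns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def sample_betas(self, sample_id: str) -> dict[str, float]:
        """Mapping probe_id -> beta for one sample (NaN kept as NaN)."""
        j = self._sample_index.get(str(sample_id))
        if j is None:
            raise ValidationError(f"unknown sample id: {sample_id!r}")
        col = self.values[:, j]
        return dict(zip(self.probe_ids, col))

    def select_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        idx = [self._probe_index[p] for p in probe_ids]
        return BetaMatrix(self.values[idx, :], [self.probe_ids[i] for i in idx], self.sample_ids)

    def select_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return BetaMatrix(self.values[:, idx], self.probe_ids, [self.sample_ids[j] for j in idx])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"


def _duplicates(items: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for x in items:
        if x in seen:
            out.append(x)
        seen.add(x)
    return out


class SampleSheet:
    """Per-sample metadata: sample_id, age (years), species, optional tissue.

    Extra columns are preserved and passed through untouched.
    """

    REQUIRED = ("sample_id", "age", "species")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in ("sample_id", "species"):
            if col not in frame.columns:
                raise ValidationError(f"sample sheet missing required column {col!r}")
            frame[col] = frame[col].astype(str)
        if "age" not in frame.columns:
            raise ValidationError("sample sheet missing required column 'age'")
        frame["age"] = pd.to_numeric(frame["age"], errors="raise")
        ids = frame["sample_id"].tolist()
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate sample ids in sheet: {_duplicates(ids)[:10]}")
        frame["species"] = frame["species"].map(normalize_species_key)
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def species(self) -> list[str]:
        return self.frame["species"].tolist()

    def row(self, sample_id: str) -> pd.Series:
        hits = self.frame[self.frame["sample_id"] == str(sample_id)]
        if hits.empty:
            raise ValidationError(f"sample {sample_id!r} not in sheet")
        return hits.iloc[0]

    def reindex(self, sample_ids: Iterable[str]) -> "SampleSheet":
        """Reorder/subset rows to match ``sample_ids`` exactly."""
        sample_ids = [str(s) for s in sample_ids]
        indexed = self.frame.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing[:10]}")
        out = indexed.loc[sample_ids].reset_index()
        return SampleSheet(out)

    def require_complete_ages(self) -> None:
        bad = self.frame.loc[self.frame["age"].isna(), "sample_id"].tolist()
        if bad:
            raise ValidationError(f"missing age for samples: {bad[:10]}")

    def __len__(self) -> int:
        return len(self.frame)


def normalize_species_key(name: str) -> str:
    """Canonical species key: trimmed, whitespace-collapsed, case-folded."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class SpeciesCharacteristics:
    """Life-history parameters of one species, all in years."""

    species: str
    max_lifespan: float  # L
    gestation: float  # g
    sexual_maturity: float  # m

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", normalize_species_key(self.species))
        L, g, m = self.max_lifespan, self.gestation, self.sexual_maturity
        if not (L > 0):
            raise ValidationError(f"{self.species}: max_lifespan must be > 0, got {L}")
        if not (g >= 0):
            raise ValidationError(f"{self.species}: gestation must be >= 0, got {g}")
        if not (m > 0):
            raise ValidationError(f"{self.species}: sexual_maturity must be > 0, got {m}")
        if not (m < L):
            raise ValidationError(
                f"{self.species}: sexual_maturity ({m}) must be < max_lifespan ({L})"
            )
        if not (g < L):
            raise ValidationError(
                f"{self.species}: gestation ({g}) must be < max_lifespan ({L})"
            )


class SpeciesTable:
    """Lookup of :class:`SpeciesCharacteristics` by normalized species key."""

    def __init__(self, records: Iterable[SpeciesCharacteristics]):
        self._by_key: dict[str, SpeciesCharacteristics] = {}
        for rec in records:
            existing = self._by_key.get(rec.species)
            if existing is not None:
                if existing == rec:
                    logger.warning("duplicate species row for %r (identical; deduplicated)", rec.species)
                    continue
                raise ValidationError(
                    f"conflicting characteristics for species {rec.species!r}: "
                    f"{existing} vs {rec}"
                )
            self._by_key[rec.species] = rec

    def __contains__(self, species: str) -> bool:
        return normalize_species_key(species) in self._by_key

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, species: str) -> SpeciesCharacteristics:
        key = normalize_species_key(species)
        if key not in self._by_key:
            raise ValidationError(f"species {key!r} not found in species table")
        return self._by_key[key]

    @property
    def species_names(self) -> list[str]:
        return list(self._by_key)


# ---------------------------------------------------------------------------
# Age transformations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransformSpec:
    """Named age transformation plus parameter overrides.

    ``params`` entries (``k``, ``m``, ``L``, ``g``) take precedence over the
    per-species defaults resolved from a :class:`SpeciesCharacteristics`
    record; any parameter a transform needs must be resolvable from one of
    the two sources.
    """

    name: str = "identity"
    params: Mapping[str, float] = field(default_factory=dict)
    clamp_epsilon: bool = False  # map relative age R to min(R, 1 - 1e-6) instead of rejecting R >= 1

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY:
            raise TransformError(
                f"unknown transform {self.name!r}; registered: {sorted(_REGISTRY)}"
            )
        object.__setattr__(self, "params", dict(self.params))

    def resolve(self, species: SpeciesCharacteristics | None) -> dict[str, float]:
        """Resolve the parameters this transform needs, erroring on gaps."""
        needed = _REGISTRY[self.name].required
        out: dict[str, float] = {}
        for sym in needed:
            if sym in self.params:
                out[sym] = float(self.params[sym])
            elif sym == "k":
                out[sym] = 1.0  # default offset of one year
            elif species is not None:
                out[sym] = {
                    "L": species.max_lifespan,
                    "g": species.gestation,
                    "m": species.sexual_maturity,
                }[sym]
            else:
                raise TransformError(
                    f"transform {self.name!r} needs parameter {sym!r} but no "
                    f"override was given and no species record is available"
                )
        return out

    @property
    def needs_species(self) -> bool:
        return any(s not in self.params and s != "k" for s in _REGISTRY[self.name].required)


@dataclass(frozen=True)
class _Transform:
    required: tuple[str, ...]
    forward: Callable[[float, dict[str, float]], float]
    inverse: Callable[[float, dict[str, float]], float]


_REGISTRY: dict[str, _Transform] = {}


def register_transform(
    name: str,
    required: tuple[str, ...],
    forward: Callable[[float, dict[str, float]], float],
    inverse: Callable[[float, dict[str, float]], float],
) -> None:
    """Add a transform to the registry (extensible for externally published
    clocks whose transform is not among the built-ins)."""
    _REGISTRY[name] = _Transform(required, forward, inverse)


def _identity_f(a: float, p: dict) -> float:
    return a


def _identity_inv(x: float, p: dict) -> float:
    return x


def _log_linear_f(a: float, p: dict) -> float:
    # log((a + k) / (m + k)) below maturity m, linear (a - m)/(m + k) above;
    # continuous with continuous first derivative at a = m.
    m, k = p["m"], p["k"]
    if a <= -k:
        raise TransformError(f"log_linear: age {a} outside domain (> {-k})")
    if a < m:
        return math.log((a + k) / (m + k))
    return (a - m) / (m + k)


def _log_linear_inv(x: float, p: dict) -> float:
    m, k = p["m"], p["k"]
    if x < 0:
        return math.exp(x) * (m + k) - k
    return x * (m + k) + m


def _relative_age(a: float, p: dict, clamp: bool) -> float:
    L, g = p["L"], p["g"]
    r = (a + g) / (L + g)
    if r <= 0:
        raise TransformError(f"relative age: age {a} at or below -gestation ({-g})")
    if clamp:
        r = min(r, 1.0 - 1e-6)
    return r


def _relative_age_f(a: float, p: dict) -> float:
    return _relative_age(a, p, clamp=False)


def _relative_age_inv(x: float, p: dict) -> float:
    L, g = p["L"], p["g"]
    if x <= 0:
        if p.get("_clamp_inverse"):
            x = 1e-9
        else:
            raise TransformError(f"relative_age inverse: value {x} outside image (must be > 0)")
    return x * (L + g) - g


def _loglog_relative_age_f(a: float, p: dict) -> float:
    r = _relative_age(a, p, clamp=p.get("_clamp", 0) > 0)
    if r >= 1:
        raise TransformError(
            f"loglog_relative_age: relative age {r} >= 1 (age {a} at/above max lifespan)"
        )
    return -math.log(-math.log(r))


def _loglog_relative_age_inv(x: float, p: dict) -> float:
    L, g = p["L"], p["g"]
    r = math.exp(-math.exp(-x))
    return r * (L + g) - g


def _relative_adult_age_f(a: float, p: dict) -> float:
    # log_linear on the relative-age scale, anchored at relative maturity
    # m' = (m + g) / (L + g).
    r = _relative_age(a, p, clamp=p.get("_clamp", 0) > 0)
    m_rel = (p["m"] + p["g"]) / (p["L"] + p["g"])
    return _log_linear_f(r, {"m": m_rel, "k": p["k"]})


def _relative_adult_age_inv(x: float, p: dict) -> float:
    m_rel = (p["m"] + p["g"]) / (p["L"] + p["g"])
    r = _log_linear_inv(x, {"m": m_rel, "k": p["k"]})
    if r <= 0:
        if p.get("_clamp_inverse"):
            r = 1e-9
        else:
            raise TransformError(f"relative_adult_age inverse: value {x} maps below -gestation")
    return r * (p["L"] + p["g"]) - p["g"]


register_transform("identity", (), _identity_f, _identity_inv)
register_transform("log_linear", ("m", "k"), _log_linear_f, _log_linear_inv)
register_transform("relative_age", ("L", "g"), _relative_age_f, _relative_age_inv)
register_transform("loglog_relative_age", ("L", "g"), _loglog_relative_age_f, _loglog_relative_age_inv)
register_transform("relative_adult_age", ("L", "g", "m", "k"), _relative_adult_age_f, _relative_adult_age_inv)

TRANSFORM_NAMES = tuple(_REGISTRY)


def transform_age(
    age: float,
    spec: TransformSpec,
    species: SpeciesCharacteristics | None = None,
) -> float:
    """Apply F(age). Strictly increasing on its domain; errors outside it."""
    params = spec.resolve(species)
    if spec.clamp_epsilon:
        params["_clamp"] = 1.0
        if spec.name == "relative_age":
            return _relative_age(age, params, clamp=True)
    return _REGISTRY[spec.name].forward(float(age), params)


def inverse_transform_age(
    x: float,
    spec: TransformSpec,
    species: SpeciesCharacteristics | None = None,
    clamp: bool = False,
) -> float:
    """Apply F^{-1}(x), mapping a transformed value back to years.

    Values outside the image of F are rejected by default; with
    ``clamp=True`` they are pulled to the nearest point of the image
    (prediction pipelines use this so a linear predictor marginally below a
    domain boundary maps to the boundary age instead of failing).
    """
    params = spec.resolve(species)
    if clamp:
        params["_clamp_inverse"] = 1.0
    return _REGISTRY[spec.name].inverse(float(x), params)


# ---------------------------------------------------------------------------
# Clock definition and application
# ---------------------------------------------------------------------------


@dataclass
class ClockDefinition:
    """A fitted (or loaded) clock: intercept, sparse coefficients, transform."""

    clock_name: str
    intercept: float
    coefficients: dict[str, float]
    transform: TransformSpec = field(default_factory=TransformSpec)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValidationError(f"clock {self.clock_name!r}: non-finite intercept")
        cleaned: dict[str, float] = {}
        for probe, coef in self.coefficients.items():
            coef = float(coef)
            if not math.isfinite(coef):
                raise ValidationError(
                    f"clock {self.clock_name!r}: non-finite coefficient for {probe!r}"
                )
            if coef != 0.0:
                cleaned[str(probe)] = coef
        self.coefficients = cleaned

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.coefficients)


def linear_predictor(
    sample_betas: Mapping[str, float],
    clock: ClockDefinition,
    missing_policy: str = "strict",
) -> tuple[float, int]:
    """Evaluate intercept + sum(coef * beta) for one sample.

    Returns ``(value, n_missing)``. Under ``strict`` (the default) any clock
    probe that is absent or NaN is an error; under ``drop_warn`` such probes
    are omitted from the sum and counted.
    """
    if missing_policy not in ("strict", "drop_warn"):
        raise ValueError(f"missing_policy must be 'strict' or 'drop_warn', got {missing_policy!r}")
    total = clock.intercept
    n_missing = 0
    for probe, coef in clock.coefficients.items():
        beta = sample_betas.get(probe)
        if beta is None or (isinstance(beta, float) and math.isnan(beta)):
            if missing_policy == "strict":
                raise ValidationError(
                    f"clock {clock.clock_name!r}: probe {probe!r} missing under strict policy"
                )
            n_missing += 1
            continue
        total += coef * float(beta)
    if n_missing:
        logger.warning(
            "clock %r: %d of %d probes missing; dropped from the linear predictor",
            clock.clock_name, n_missing, clock.n_coefficients,
        )
    return total, n_missing


def predict_age(
    betas: BetaMatrix,
    clock: ClockDefinition,
    sheet: SampleSheet | None = None,
    species_table: SpeciesTable | None = None,
    missing_policy: str = "strict",
) -> pd.DataFrame:
    """Apply a clock to every sample of a beta matrix.

    Returns a DataFrame indexed like ``betas.sample_ids`` with columns
    ``linear_predictor``, ``dnam_age`` (years) and ``n_missing_probes``.
    The sheet and species table are only needed when the clock's transform
    requires species parameters not fixed in the transform spec.
    """
    spec = clock.transform
    needs_species = spec.needs_species
    if needs_species and (sheet is None or species_table is None):
        raise ValidationError(
            f"transform {spec.name!r} needs species parameters: provide a "
            f"sample sheet and species table"
        )
    # Vectorized evaluation of the linear part.
    probe_rows = []
    coefs = []
    missing_probes = []
    for probe, coef in clock.coefficients.items():
        idx = betas._probe_index.get(probe)
        if idx is None:
            missing_probes.append(probe)
        else:
            probe_rows.append(idx)
            coefs.append(coef)
    if missing_probes and missing_policy == "strict":
        raise ValidationError(
            f"clock {clock.clock_name!r}: {len(missing_probes)} probe(s) absent "
            f"from the beta matrix under strict policy; first: {missing_probes[:10]}"
        )
    sub = betas.values[probe_rows, :] if probe_rows else np.zeros((0, betas.n_samples))
    coef_vec = np.asarray(coefs)

    records = []
    for j, sample_id in enumerate(betas.sample_ids):
        col = sub[:, j]
        nan_mask = np.isnan(col)
        n_missing = len(missing_probes) + int(nan_mask.sum())
        if nan_mask.any() and missing_policy == "strict":
            raise ValidationError(
                f"clock {clock.clock_name!r}: sample {sample_id!r} has missing "
                f"beta for clock probe(s) under strict policy"
            )
        lp = clock.intercept + float(np.dot(coef_vec[~nan_mask], col[~nan_mask]))
        species = None
        if needs_species:
            row = sheet.row(sample_id)
            species = species_table.get(row["species"])
        dnam = inverse_transform_age(lp, spec, species, clamp=True)
        records.append((sample_id, lp, dnam, n_missing))
    if missing_probes:
        logger.warning(
            "clock %r: %d clock probe(s) absent from input matrix (drop_warn)",
            clock.clock_name, len(missing_probes),
        )
    out = pd.DataFrame.from_records(
        records, columns=["sample_id", "linear_predictor", "dnam_age", "n_missing_probes"]
    ).set_index("sample_id")
    return out
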