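"""Readers, writers and validators for the toolkit's table dialects.

Dialects: clock coefficient files (CSV, columns ``var``/``coef`` with one
``(Intercept)`` row and '#'-prefixed metadata header lines), beta matrices
(CSV/TSV, row ids in the first column), sample sheets, species tables
(AnAge-style life-history parameters), and detection-p matrices. Readers
reject malformed input with located error messages; writers emit a strict,
deterministic dialect that round-trips bit-faithfully.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    BetaMatrix,
    ClockDefinition,
    SampleSheet,
    SpeciesCharacteristics,
    SpeciesTable,
    TransformSpec,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_clock",
    "write_clock",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "read_species_table",
    "read_detection_p",
    "read_probe_list",
    "ClockRegistry",
    "get_clock_registry",
]

INTERCEPT_TOKEN = "(Intercept)"

# Published clock CSVs vary in column naming; accept these aliases on read.
_VAR_ALIASES = {"var", "cpg", "probe", "probe_id", "cpgmarker"}
_COEF_ALIASES = {"coef", "beta", "coefficient", "coefficienttraining"}

_SHEET_ALIASES = {
    "sample_id": {"sample_id", "sampleid", "sample", "basename", "id"},
    "age": {"age", "age_years", "chronological_age"},
    "species": {"species", "specieslatinname", "species_latin_name", "organism"},
    "tissue": {"tissue", "tissue_type"},
}

_SPECIES_ALIASES = {
    "species": {"species", "specieslatinname", "species_latin_name", "organism"},
    "max_lifespan": {"max_lifespan", "maxagecaped", "maximum_lifespan", "maxlifespan", "maxage"},
    "gestation": {"gestation", "gestation_years", "gestationtimeinyears", "gestation_time"},
    "sexual_maturity": {
        "sexual_maturity", "age_sexual_maturity", "averagedmaturity", "averagedmaturity.yrs",
        "maturity_years",
    },
}


def _sniff_sep(path: str | Path) -> str:
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    if path.suffix.lower() == ".csv":
        return ","
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def _canonicalize_columns(columns, alias_map: dict[str, set[str]]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        key = str(col).strip().casefold()
        for canonical, aliases in alias_map.items():
            if key in aliases:
                mapping[col] = canonical
                break
    return mapping


# ---------------------------------------------------------------------------
# Clock files
# ---------------------------------------------------------------------------


def read_clock(path: str | Path) -> ClockDefinition:
    """Load a clock coefficient CSV.

    Metadata rides in '#'-prefixed ``key=value`` header lines (clock_name,
    transform, transform_params as JSON). Clocks with no declared transform
    default to identity with a warning. Errors carry line numbers.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()

    try:
        frame = pd.read_csv(path, comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValidationError(f"{path}: cannot parse clock CSV: {exc}") from exc
    rename = _canonicalize_columns(frame.columns, {"var": _VAR_ALIASES, "coef": _COEF_ALIASES})
    frame = frame.rename(columns=rename)
    for col in ("var", "coef"):
        if col not in frame.columns:
            raise ValidationError(
                f"{path}: clock file missing required column {col!r} "
                f"(accepted aliases: {sorted(_VAR_ALIASES if col == 'var' else _COEF_ALIASES)})"
            )

    # Line numbers: 1-based file lines; +1 for the column header row.
    data_start = header_lines + 2
    line_of = {i: data_start + i for i in range(len(frame))}

    coefs: dict[str, float] = {}
    intercept: float | None = None
    intercept_lines: list[int] = []
    seen: dict[str, int] = {}
    for i, row in frame.iterrows():
        var = str(row["var"])
        raw = row["coef"]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}:{line_of[i]}: unparseable coefficient {raw!r} for {var!r}")
        if not np.isfinite(value):
            raise ValidationError(f"{path}:{line_of[i]}: non-finite coefficient for {var!r}")
        if var == INTERCEPT_TOKEN:
            intercept_lines.append(line_of[i])
            intercept = value
            continue
        if var in seen:
            raise ValidationError(
                f"{path}:{line_of[i]}: duplicate probe {var!r} (first at line {seen[var]})"
            )
        seen[var] = line_of[i]
        coefs[var] = value
    if intercept is None:
        raise ValidationError(f"{path}: no '(Intercept)' row found")
    if len(intercept_lines) > 1:
        raise ValidationError(
            f"{path}: multiple '(Intercept)' rows at lines {intercept_lines}"
        )
    n_zero = sum(1 for v in coefs.values() if v == 0.0)
    if n_zero:
        logger.info("%s: dropping %d zero coefficient(s)", path, n_zero)

    transform_name = meta.get("transform")
    if transform_name is None:
        logger.warning("%s: no transform declared; defaulting to identity", path)
        transform_name = "identity"
    params = {}
    if "transform_params" in meta and meta["transform_params"]:
        try:
            params = json.loads(meta["transform_params"])
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: bad transform_params JSON: {exc}") from exc
    transform = TransformSpec(name=transform_name, params=params)
    provenance = {k: v for k, v in meta.items()
                  if k not in ("clock_name", "transform", "transform_params")}
    return ClockDefinition(
        clock_name=meta.get("clock_name", path.stem),
        intercept=intercept,
        coefficients=coefs,
        transform=transform,
        provenance=provenance,
    )


def write_clock(clock: ClockDefinition, path: str | Path) -> None:
    """Write the strict clock dialect: metadata header, intercept row first,
    probes in lexicographic order, floats at 17 significant digits."""
    path = Path(path)
    lines = [f"# clock_name={clock.clock_name}"]
    lines.append(f"# transform={clock.transform.name}")
    if clock.transform.params:
        lines.append(f"# transform_params={json.dumps(clock.transform.params, sort_keys=True)}")
    for key in sorted(clock.provenance):
        value = clock.provenance[key]
        if isinstance(value, (str, int, float, bool)):
            lines.append(f"# {key}={value}")
    lines.append("var,coef")
    lines.append(f"{INTERCEPT_TOKEN},{clock.intercept:.17g}")
    for probe in sorted(clock.coefficients):
        lines.append(f"{probe},{clock.coefficients[probe]:.17g}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Beta matrices and detection-p matrices
# ---------------------------------------------------------------------------

_NA_TOKENS = ["", "NA", "na", "Na", "NaN", "nan", "NAN"]


def read_beta_matrix(path: str | Path, orientation: str = "probes_in_rows") -> BetaMatrix:
    """Read a CSV/TSV beta matrix (first column = row ids).

    ``orientation`` declares whether rows are probes or samples; the result
    is always probes x samples. Values outside [0, 1] are rejected with the
    offending probe/sample named.
    """
    if orientation not in ("probes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sniff_sep(path)
    frame = pd.read_csv(path, sep=sep, index_col=0, na_values=_NA_TOKENS,
                        keep_default_na=False, float_precision="round_trip")
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate row ids: {dupes[:10]}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate column ids: {dupes[:10]}")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric beta value: {exc}") from exc
    if orientation == "samples_in_rows":
        frame = frame.T
        values = values.T
    bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 1)))
    if bad.size:
        offenders = [
            f"(probe={frame.index[i]}, sample={frame.columns[j]}, value={values[i, j]!r})"
            for i, j in bad[:10]
        ]
        raise ValidationError(
            f"{path}: {len(bad)} beta value(s) outside [0, 1]; first offenders: "
            + "; ".join(offenders)
        )
    return BetaMatrix(values, frame.index.astype(str), frame.columns.astype(str))


def write_beta_matrix(betas: BetaMatrix, path: str | Path) -> None:
    """Write probes x samples CSV at full float precision (17 sig digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("probe_id," + ",".join(betas.sample_ids) + "\n")
        for i, probe in enumerate(betas.probe_ids):
            cells = [
                "" if np.isnan(v) else f"{v:.17g}" for v in betas.values[i]
            ]
            fh.write(probe + "," + ",".join(cells) + "\n")


def read_detection_p(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples detection p-value matrix (CSV/TSV)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0,
                        na_values=_NA_TOKENS, keep_default_na=False,
                        float_precision="round_trip")
    values = frame.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(values) & ((values < 0) | (values > 1)))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"{path}: detection p-value outside [0, 1] at probe {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}: {values[i, j]!r}"
        )
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def read_probe_list(path: str | Path) -> list[str]:
    """One probe id per line (mappability annotation files)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Sample sheets and species tables
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path, required: tuple[str, ...] = ("sample_id", "age", "species")) -> SampleSheet:
    """Read a sample sheet CSV; column names matched case-insensitively via
    a canonicalization map. Extra columns pass through."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), na_values=_NA_TOKENS, keep_default_na=False)
    rename = _canonicalize_columns(frame.columns, _SHEET_ALIASES)
    frame = frame.rename(columns=rename)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: sample sheet missing required column(s) {missing}")
    if "age" in frame.columns:
        for i, raw in enumerate(frame["age"]):
            if pd.isna(raw) or raw == "":
                continue
            try:
                float(raw)
            except (TypeError, ValueError):
                raise ValidationError(f"{path}:{i + 2}: non-numeric age {raw!r}")
        frame["age"] = pd.to_numeric(frame["age"], errors="coerce")
    return SampleSheet(frame)


def read_species_table(path: str | Path) -> SpeciesTable:
    """Read AnAge-style species characteristics (lifespan, gestation,
    maturity — all in years). Duplicate identical rows are deduplicated with
    a warning; conflicting duplicates are an error."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), na_values=_NA_TOKENS, keep_default_na=False)
    rename = _canonicalize_columns(frame.columns, _SPECIES_ALIASES)
    frame = frame.rename(columns=rename)
    missing = [c for c in ("species", "max_lifespan", "gestation", "sexual_maturity")
               if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: species table missing required column(s) {missing}")
    records = []
    for i, row in frame.iterrows():
        line = i + 2
        vals = {}
        for col in ("max_lifespan", "gestation", "sexual_maturity"):
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError):
                raise ValidationError(f"{path}:{line}: non-numeric {col} {row[col]!r}")
        try:
            records.append(SpeciesCharacteristics(species=str(row["species"]), **vals))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{line}: {exc}") from exc
    return SpeciesTable(records)


# ---------------------------------------------------------------------------
# Clock registry
# ---------------------------------------------------------------------------


@dataclass
class ClockRegistry:
    """Index of available clock files (bundled fixtures + user directory)."""

    table: pd.DataFrame  # clock_name, species_scope, tissue_scope, transform, citation, path

    def names(self) -> list[str]:
        return self.table["clock_name"].tolist()

    def load(self, clock_name: str) -> ClockDefinition:
        hits = self.table[self.table["clock_name"] == clock_name]
        if hits.empty:
            raise ValidationError(
                f"unknown clock {clock_name!r}; available: {self.names()}"
            )
        return read_clock(hits.iloc[0]["path"])


def _bundled_clock_dir() -> Path:
    return Path(str(resources.files("methclock").joinpath("data/clocks")))


def get_clock_registry(user_dir: str | Path | None = None) -> ClockRegistry:
    """Scan bundled fixture clocks plus an optional user directory of
    conforming CSVs. A malformed clock file fails the registry build loudly,
    naming the file."""
    rows = []
    dirs = [_bundled_clock_dir()]
    if user_dir is not None:
        dirs.append(Path(user_dir))
    seen: set[str] = set()
    for directory in dirs:
        if not directory.is_dir():
            continue
        for path in sorted(directory.glob("*.csv")):
            try:
                clock = read_clock(path)
            except ValidationError as exc:
                raise ValidationError(f"registry build failed on {path}: {exc}") from exc
            if clock.clock_name in seen:
                raise ValidationError(
                    f"registry build failed: duplicate clock_name {clock.clock_name!r} at {path}"
                )
            seen.add(clock.clock_name)
            rows.append(
                {
                    "clock_name": clock.clock_name,
                    "species_scope": clock.provenance.get("species_scope", "any"),
                    "tissue_scope": clock.provenance.get("tissue_scope", "any"),
                    "transform": clock.transform.name,
                    "citation": clock.provenance.get("citation", ""),
                    "path": str(path),
                }
            )
    return ClockRegistry(table=pd.DataFrame(rows, columns=[
        "clock_name", "species_scope", "tissue_scope", "transform", "citation", "path"
    ]))
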