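"""Data model, readers/writers and validation for observation registers.

Historical weather registers (18th-century style) record air temperature in
degrees Fahrenheit and wind as an ordinal force code on a station-specific
scale; contemporary station series record temperature in Celsius and wind
speed in m/s at a stated anemometer height.  Both are carried by the same
record type, with units and wind representation declared once per file by a
schema sidecar — never inferred per row.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional

from pydantic import BaseModel, model_validator

__all__ = [
    "ObservationRecord",
    "ObservationSeries",
    "WindScale",
    "RegisterSchema",
    "ValidationIssue",
    "RegisterError",
    "SchemaError",
    "get_scale",
    "available_scales",
    "read_register",
    "write_register",
    "validate_series",
]

HOURS_LT = ("08:00", "14:00", "15:00")

#: physical plausibility bounds for air temperature, degrees Celsius
T_MIN_C, T_MAX_C = -80.0, 60.0

# minus-sign variants seen in transcriptions: ASCII hyphen-minus, Unicode
# minus (U+2212) and the modifier-letter minus (U+02D7)
_MINUS_VARIANTS = {"−": "-", "˗": "-"}


class RegisterError(ValueError):
    """Raised for invalid register content (duplicates, mixed units...)."""


class SchemaError(ValueError):
    """Raised for an inconsistent or incomplete register schema."""


def normalize_minus(token: str) -> str:
    """Normalize typographic minus-sign variants to ASCII hyphen-minus."""
    for variant, repl in _MINUS_VARIANTS.items():
        token = token.replace(variant, repl)
    return token


# ---------------------------------------------------------------------------
# wind scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindScale:
    """Ordinal wind-force scale: force code -> representative speed (m/s, 10 m).

    The mapping must be strictly increasing in the force code and all speeds
    non-negative; codes form the scale's domain.
    """

    scale_id: str
    mapping: dict[int, float]

    def __post_init__(self) -> None:
        codes = sorted(self.mapping)
        speeds = [self.mapping[c] for c in codes]
        if any(s < 0 for s in speeds):
            raise ValueError(f"scale {self.scale_id!r}: negative speed")
        if any(b <= a for a, b in zip(speeds, speeds[1:])):
            raise ValueError(
                f"scale {self.scale_id!r}: speeds must strictly increase with force"
            )
        object.__setattr__(self, "mapping", dict(zip(codes, speeds)))

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted(self.mapping))

    def speed(self, force: int) -> float:
        try:
            return self.mapping[int(force)]
        except (KeyError, TypeError) as exc:
            raise ValueError(
                f"force code {force!r} outside domain {self.codes} "
                f"of scale {self.scale_id!r}"
            ) from exc

    def __contains__(self, force: object) -> bool:
        return isinstance(force, (int, float)) and int(force) == force and int(force) in self.mapping


def _load_builtin_scales() -> dict[str, WindScale]:
    raw = json.loads(
        resources.files("histbioclim.data").joinpath("wind_scales.json").read_text()
    )
    out: dict[str, WindScale] = {}
    for entry in raw["scales"]:
        scale = WindScale(
            scale_id=entry["scale_id"],
            mapping={int(k): float(v) for k, v in entry["mapping"].items()},
        )
        out[scale.scale_id] = scale
        for alias in entry.get("aliases", ()):
            out[alias] = scale
    return out


_BUILTIN_SCALES = _load_builtin_scales()


def get_scale(scale_id: str) -> WindScale:
    """Return a built-in wind scale by id or alias."""
    try:
        return _BUILTIN_SCALES[scale_id]
    except KeyError:
        raise SchemaError(
            f"unknown wind scale {scale_id!r}; known: {sorted(set(available_scales()))}"
        ) from None


def available_scales() -> list[str]:
    return sorted({s.scale_id for s in _BUILTIN_SCALES.values()})


# ---------------------------------------------------------------------------
# records and series
# ---------------------------------------------------------------------------

@dataclass
class ObservationRecord:
    """One raw observation at a (date, local-hour) slot.

    ``temperature`` / ``wind`` are ``None`` when the register marked them
    missing.  ``wind_scale_id`` is required iff ``wind_kind`` is
    ``ordinal_force``; ``anemometer_height_m`` iff ``wind_kind`` is
    ``speed_ms``.
    """

    date: dt.date
    hour_lt: str
    temperature: Optional[float]
    temperature_unit: Literal["F", "C"]
    wind: Optional[float]
    wind_kind: Literal["ordinal_force", "speed_ms"]
    wind_scale_id: Optional[str] = None
    anemometer_height_m: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hour_lt not in HOURS_LT:
            raise ValueError(f"hour_lt must be one of {HOURS_LT}, got {self.hour_lt!r}")
        if self.wind_kind == "ordinal_force" and not self.wind_scale_id:
            raise SchemaError("ordinal_force wind requires wind_scale_id")
        if self.wind_kind == "speed_ms":
            if self.anemometer_height_m is None:
                raise SchemaError("speed_ms wind requires anemometer_height_m")
            if self.anemometer_height_m <= 0:
                raise ValueError("anemometer_height_m must be > 0")

    @property
    def temperature_c(self) -> Optional[float]:
        if self.temperature is None:
            return None
        if self.temperature_unit == "C":
            return float(self.temperature)
        return (float(self.temperature) - 32.0) * 5.0 / 9.0


@dataclass
class ObservationSeries:
    """Date-ordered collection of observations from one station/register."""

    station_name: str
    records: list[ObservationRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(r.date, r.hour_lt) for r in self.records]
        dup = {k for k in keys if keys.count(k) > 1}
        if dup:
            d, h = sorted(dup)[0]
            raise RegisterError(f"duplicate observation slot {d.isoformat()} {h}")
        self.records.sort(key=lambda r: (r.date, r.hour_lt))

    @property
    def period(self) -> Optional[tuple[dt.date, dt.date]]:
        if not self.records:
            return None
        return self.records[0].date, self.records[-1].date

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def at_hour(self, hour_lt: str) -> list[ObservationRecord]:
        return [r for r in self.records if r.hour_lt == hour_lt]


# ---------------------------------------------------------------------------
# schema sidecar
# ---------------------------------------------------------------------------

class RegisterSchema(BaseModel):
    """Declares how to interpret one register CSV.

    One temperature unit and one wind representation per file.  Column names
    default to the canonical ``date, hour, temp, wind``.
    """

    station_name: str = "unknown"
    temperature_unit: Literal["F", "C"]
    wind_kind: Literal["ordinal_force", "speed_ms"]
    wind_scale_id: Optional[str] = None
    anemometer_height_m: Optional[float] = None
    missing_token: str = "NA"
    date_column: str = "date"
    hour_column: str = "hour"
    temp_column: str = "temp"
    wind_column: str = "wind"

    @model_validator(mode="after")
    def _check_wind_fields(self) -> "RegisterSchema":
        if self.wind_kind == "ordinal_force":
            if not self.wind_scale_id:
                raise SchemaError("wind_kind=ordinal_force requires wind_scale_id")
            get_scale(self.wind_scale_id)  # fail early on unknown scale
        else:
            if self.anemometer_height_m is None:
                raise SchemaError("wind_kind=speed_ms requires anemometer_height_m")
            if self.anemometer_height_m <= 0:
                raise SchemaError("anemometer_height_m must be > 0")
        return self


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_register(path, schema: RegisterSchema) -> ObservationSeries:
    """Read a register CSV into a validated, date-ordered series.

    Unparseable rows are collected under ``series.metadata['unparsed_rows']``
    (list of ``(line_number, reason)``), never silently dropped.  A duplicate
    (date, hour) slot raises :class:`RegisterError` naming the slot.
    """
    records: list[ObservationRecord] = []
    unparsed: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in (schema.date_column, schema.hour_column,
                    schema.temp_column, schema.wind_column):
            if col not in header:
                raise SchemaError(f"missing mandatory column {col!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, schema))
            except (ValueError, KeyError) as exc:
                unparsed.append((lineno, str(exc)))
    series = ObservationSeries(
        station_name=schema.station_name,
        records=records,
        metadata={"schema": schema.model_dump(), "source": str(path)},
    )
    if unparsed:
        series.metadata["unparsed_rows"] = unparsed
    return series


def _parse_row(row: dict, schema: RegisterSchema) -> ObservationRecord:
    date = dt.date.fromisoformat(row[schema.date_column].strip())
    hour = row[schema.hour_column].strip()
    t_tok = normalize_minus(row[schema.temp_column].strip())
    w_tok = normalize_minus(row[schema.wind_column].strip())
    temp = None if t_tok == schema.missing_token or t_tok == "" else float(t_tok)
    if w_tok == schema.missing_token or w_tok == "":
        wind: Optional[float] = None
    elif schema.wind_kind == "ordinal_force":
        wind = float(int(w_tok))
    else:
        wind = float(w_tok)
    return ObservationRecord(
        date=date,
        hour_lt=hour,
        temperature=temp,
        temperature_unit=schema.temperature_unit,
        wind=wind,
        wind_kind=schema.wind_kind,
        wind_scale_id=schema.wind_scale_id,
        anemometer_height_m=schema.anemometer_height_m,
    )


def write_register(series: ObservationSeries, path) -> None:
    """Write a series as a canonical register CSV (header always present).

    The file carries one temperature unit and one wind representation;
    mixing within the series raises :class:`RegisterError`.
    """
    units = {r.temperature_unit for r in series.records}
    kinds = {r.wind_kind for r in series.records}
    if len(units) > 1:
        raise RegisterError(f"series mixes temperature units {sorted(units)}")
    if len(kinds) > 1:
        raise RegisterError(f"series mixes wind representations {sorted(kinds)}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "hour", "temp", "wind"])
        for r in series.records:
            writer.writerow([
                r.date.isoformat(),
                r.hour_lt,
                "NA" if r.temperature is None else _fmt(r.temperature),
                "NA" if r.wind is None else (
                    str(int(r.wind)) if r.wind_kind == "ordinal_force" else _fmt(r.wind)
                ),
            ])


def _fmt(x: float) -> str:
    return repr(float(x))


def schema_for(series: ObservationSeries) -> RegisterSchema:
    """Build the schema sidecar matching a homogeneous series."""
    if not series.records:
        raise RegisterError("cannot infer schema from an empty series")
    r = series.records[0]
    return RegisterSchema(
        station_name=series.station_name,
        temperature_unit=r.temperature_unit,
        wind_kind=r.wind_kind,
        wind_scale_id=r.wind_scale_id,
        anemometer_height_m=r.anemometer_height_m,
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    kind: Literal["gap", "out_of_range", "unknown_force_code"]
    date: dt.date
    hour_lt: str
    message: str


def validate_series(series: ObservationSeries) -> list[ValidationIssue]:
    """Return typed data-quality issues; pure (the series is not mutated).

    Checks: temperature within physical range after conversion to Celsius,
    force codes within their scale's domain, calendar gaps between
    consecutive observation dates.
    """
    issues: list[ValidationIssue] = []
    prev_date: Optional[dt.date] = None
    for r in series.records:
        t_c = r.temperature_c
        if t_c is not None and not (T_MIN_C <= t_c <= T_MAX_C):
            issues.append(ValidationIssue(
                "out_of_range", r.date, r.hour_lt,
                f"temperature {t_c:.1f} degC outside [{T_MIN_C}, {T_MAX_C}]",
            ))
        if r.wind is not None and r.wind_kind == "ordinal_force":
            scale = get_scale(r.wind_scale_id)
            if r.wind not in scale:
                issues.append(ValidationIssue(
                    "unknown_force_code", r.date, r.hour_lt,
                    f"force code {r.wind:g} not in scale {scale.scale_id!r} "
                    f"domain {scale.codes}",
                ))
        if prev_date is not None and (r.date - prev_date).days > 1:
            issues.append(ValidationIssue(
                "gap", r.date, r.hour_lt,
                f"{(r.date - prev_date).days - 1} missing day(s) before {r.date}",
            ))
        prev_date = r.date
    return issues
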