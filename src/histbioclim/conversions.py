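"""Unit and representation conversions for observation series.

Temperature is converted Fahrenheit -> Celsius; ordinal wind-force codes are
mapped to representative speeds at 10 m via their scale's table; wind speeds
are moved between heights with the empirical power-law profile

    v(h2) = v(h1) * (h2 / h1) ** alpha,   alpha = 0.2 by default,

which is the convention used for coastal stations when only a single-level
wind is available.  ``standardize`` composes the three into canonical
per-observation values: t (degC), v10 (m/s at 10 m, wind-chill input) and
v12 (m/s at 1.2 m, chest height, clothing-insulation input).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

from .registers import ObservationSeries, WindScale, get_scale

__all__ = [
    "StandardObservation",
    "WIND_PROFILE_EXPONENT",
    "CHEST_HEIGHT_M",
    "REFERENCE_HEIGHT_M",
    "fahrenheit_to_celsius",
    "wind_force_to_speed10",
    "adjust_wind_height",
    "standardize",
]

WIND_PROFILE_EXPONENT = 0.2
CHEST_HEIGHT_M = 1.2
REFERENCE_HEIGHT_M = 10.0


@dataclass(frozen=True)
class StandardObservation:
    """One observation in canonical units.

    ``t_c`` in degC; ``v10``/``v12`` in m/s at 10 m / 1.2 m.  ``None`` marks
    a missing value.  ``wind_source`` records whether the winds derive from
    an ordinal force code, a measured speed, or are absent.
    """

    date: dt.date
    hour_lt: str
    t_c: Optional[float]
    v10: Optional[float]
    v12: Optional[float]
    t_converted: bool = False
    wind_source: str = "missing"  # "ordinal_force" | "speed_ms" | "missing"


def fahrenheit_to_celsius(t_f: float) -> float:
    """Convert degrees Fahrenheit to degrees Celsius: (t_f - 32) * 5/9."""
    return (float(t_f) - 32.0) * 5.0 / 9.0


def wind_force_to_speed10(force: int, scale: WindScale) -> float:
    """Representative wind speed (m/s at 10 m) for an ordinal force code.

    Exact table lookup; a code outside the scale's domain raises ValueError
    naming the scale and code.
    """
    return scale.speed(force)


def adjust_wind_height(v: float, h_from: float, h_to: float,
                       exponent: float = WIND_PROFILE_EXPONENT) -> float:
    """Move a wind speed between measurement heights by the power-law profile."""
    if v < 0:
        raise ValueError(f"wind speed must be >= 0, got {v}")
    if h_from <= 0 or h_to <= 0:
        raise ValueError(f"heights must be > 0, got h_from={h_from}, h_to={h_to}")
    return float(v) * (h_to / h_from) ** exponent


def standardize(series: ObservationSeries,
                exponent: float = WIND_PROFILE_EXPONENT) -> list[StandardObservation]:
    """Standardize a series to (t degC, v10, v12) per observation.

    Ordinal winds go through the scale table (valid at 10 m) and are then
    height-adjusted to 1.2 m; measured speeds are adjusted from the
    anemometer height to both reference heights.  Missing inputs propagate
    as missing outputs; the output has exactly one entry per input record.
    """
    out: list[StandardObservation] = []
    for r in series.records:
        t_c = r.temperature_c
        v10: Optional[float] = None
        v12: Optional[float] = None
        source = "missing"
        if r.wind is not None:
            if r.wind_kind == "ordinal_force":
                scale = get_scale(r.wind_scale_id)
                v10 = wind_force_to_speed10(int(r.wind), scale)
                v12 = adjust_wind_height(v10, REFERENCE_HEIGHT_M, CHEST_HEIGHT_M,
                                         exponent)
                source = "ordinal_force"
            else:
                h = float(r.anemometer_height_m)
                v10 = adjust_wind_height(r.wind, h, REFERENCE_HEIGHT_M, exponent)
                v12 = adjust_wind_height(r.wind, h, CHEST_HEIGHT_M, exponent)
                source = "speed_ms"
        out.append(StandardObservation(
            date=r.date,
            hour_lt=r.hour_lt,
            t_c=t_c,
            v10=v10,
            v12=v12,
            t_converted=(r.temperature_unit == "F" and t_c is not None),
            wind_source=source,
        ))
    return out
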