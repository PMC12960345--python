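"""Synthetic register generator emulating a west-Greenland coastal station.

The original registers survive only as archival manuscripts, so every stage
of the pipeline is exercised against synthetic series with the statistical
structure the analysis assumes:

* a seasonal cycle of afternoon air temperature, interpolated from monthly
  target means (defaults emulate Nuuk's 1991-2020 15:00 LT climatology);
* AR(1) day-to-day temperature anomalies — the minimal model producing a
  realistic distribution of interdiurnal changes, which is what the
  stimulus classification consumes;
* per-month Weibull wind speeds at 10 m, discretized to ordinal force
  codes in the historical modes;
* historical-register quirks: twice-daily observations (08:00, 14:00 LT),
  Fahrenheit readings rounded to 0.5 degF, and missingness as contiguous
  date blocks (voyages, gaps) rather than i.i.d. dropout.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .conversions import CHEST_HEIGHT_M, REFERENCE_HEIGHT_M, adjust_wind_height
from .registers import ObservationRecord, ObservationSeries, WindScale, get_scale

__all__ = [
    "SyntheticConfig",
    "NUUK_MONTHLY_T15_C",
    "NUUK_MONTHLY_V10_MS",
    "simulate_contemporary",
    "simulate_historical",
    "discretize_wind",
    "seasonal_cycle",
]

#: default afternoon (15:00 LT) monthly mean temperature targets, degC,
#: Jan..Dec — a Nuuk-like coastal-Arctic climatology
NUUK_MONTHLY_T15_C = (-7.6, -8.2, -7.4, -2.6, 2.3, 6.3,
                      8.9, 8.2, 3.9, 0.1, -3.2, -5.3)

#: default monthly mean wind-speed targets at 1.2 m, m/s, Jan..Dec
_NUUK_MONTHLY_V12_MS = (4.6, 4.5, 4.6, 4.1, 3.6, 3.5,
                        3.4, 3.6, 3.9, 3.8, 4.3, 4.5)

#: the same targets expressed at 10 m via the 0.2-power profile
NUUK_MONTHLY_V10_MS = tuple(
    adjust_wind_height(v, CHEST_HEIGHT_M, REFERENCE_HEIGHT_M)
    for v in _NUUK_MONTHLY_V12_MS
)


class SyntheticConfig(BaseModel):
    """Parameters of the synthetic station.

    ``phi``/``sigma`` are the AR(1) coefficient and innovation SD (degC) of
    the daily temperature anomaly; the anomaly's marginal SD is
    sigma / sqrt(1 - phi^2).  Wind is Weibull per month with the given shape
    and a scale chosen so the distribution mean hits the monthly target.
    """

    mode: Literal["contemporary", "historical_1767", "historical_1789"] = "contemporary"
    seed: int = 0
    start_year: int = 1991
    n_years: int = 30
    monthly_t_c: Sequence[float] = NUUK_MONTHLY_T15_C
    monthly_v10_ms: Sequence[float] = NUUK_MONTHLY_V10_MS
    phi: float = 0.7
    sigma: float = 2.5
    weibull_shape: float = 2.0
    missing_rate: float = 0.0
    missing_block_days: int = 10
    morning_offset_c: float = -1.5
    fahrenheit_rounding: float = 0.5
    station_name: str = "synthetic"

    @model_validator(mode="after")
    def _check(self) -> "SyntheticConfig":
        if not abs(self.phi) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.sigma <= 0 or self.weibull_shape <= 0:
            raise ValueError("sigma and weibull_shape must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.monthly_t_c) != 12 or len(self.monthly_v10_ms) != 12:
            raise ValueError("monthly targets must have 12 entries (Jan..Dec)")
        if any(v <= 0 for v in self.monthly_v10_ms):
            raise ValueError("monthly wind targets must be > 0")
        return self

    @property
    def scale(self) -> Optional[WindScale]:
        if self.mode == "historical_1767":
            return get_scale("scale_1767")
        if self.mode == "historical_1789":
            return get_scale("scale_1789")
        return None


def seasonal_cycle(dates: Sequence[dt.date],
                   monthly_means: Sequence[float]) -> np.ndarray:
    """Daily values from monthly means by periodic linear interpolation.

    Monthly targets are anchored at mid-month (day-of-year of the 15th) and
    interpolated around the calendar circle, so monthly averages of the
    cycle track the targets closely.
    """
    anchors = np.array([dt.date(2000, m, 15).timetuple().tm_yday
                        for m in range(1, 13)], dtype=float)
    vals = np.asarray(monthly_means, dtype=float)
    # wrap one anchor on each side for periodicity (366-day reference)
    xs = np.concatenate([[anchors[-1] - 366.0], anchors, [anchors[0] + 366.0]])
    ys = np.concatenate([[vals[-1]], vals, [vals[0]]])
    doy = np.array([dt.date(2000, d.month, d.day).timetuple().tm_yday
                    for d in dates], dtype=float)
    return np.interp(doy, xs, ys)


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) path: x0 drawn from the marginal distribution."""
    x = np.empty(n)
    marginal_sd = sigma / math.sqrt(1.0 - phi * phi)
    x[0] = rng.normal(0.0, marginal_sd)
    eps = rng.normal(0.0, sigma, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def _wind_speeds(dates: Sequence[dt.date], config: SyntheticConfig,
                 rng: np.random.Generator) -> np.ndarray:
    k = config.weibull_shape
    gamma = math.gamma(1.0 + 1.0 / k)
    scales = np.array([config.monthly_v10_ms[d.month - 1] / gamma for d in dates])
    return scales * rng.weibull(k, size=len(dates))


def _date_range(config: SyntheticConfig) -> list[dt.date]:
    start = dt.date(config.start_year, 1, 1)
    end = dt.date(config.start_year + config.n_years - 1, 12, 31)
    return [start + dt.timedelta(days=i)
            for i in range((end - start).days + 1)]


def _missing_mask(n: int, config: SyntheticConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Contiguous missing date blocks totalling ~missing_rate of the days."""
    mask = np.zeros(n, dtype=bool)
    if config.missing_rate <= 0:
        return mask
    target = int(round(config.missing_rate * n))
    block = max(1, config.missing_block_days)
    while mask.sum() < target:
        start = int(rng.integers(0, n))
        mask[start:start + block] = True
    return mask


def simulate_contemporary(config: SyntheticConfig) -> ObservationSeries:
    """Daily 15:00 LT series: temperature (degC) and wind speed (m/s, 10 m)."""
    if config.mode != "contemporary":
        raise ValueError(f"mode must be 'contemporary', got {config.mode!r}")
    rng = np.random.default_rng(config.seed)
    dates = _date_range(config)
    cycle = seasonal_cycle(dates, config.monthly_t_c)
    temps = cycle + _ar1(len(dates), config.phi, config.sigma, rng)
    winds = _wind_speeds(dates, config, rng)
    missing = _missing_mask(len(dates), config, rng)
    records = [
        ObservationRecord(
            date=d, hour_lt="15:00",
            temperature=round(float(t), 1), temperature_unit="C",
            wind=round(float(v), 1), wind_kind="speed_ms",
            anemometer_height_m=REFERENCE_HEIGHT_M,
        )
        for d, t, v, miss in zip(dates, temps, winds, missing) if not miss
    ]
    return ObservationSeries(
        station_name=config.station_name, records=records,
        metadata={"synthetic": True, "config": config.model_dump()},
    )


def simulate_historical(config: SyntheticConfig) -> ObservationSeries:
    """Twice-daily register (08:00, 14:00 LT): degF readings, ordinal winds.

    Temperatures are rounded to the configured manuscript precision
    (default 0.5 degF); winds are drawn continuously at 10 m and discretized
    to the mode's ordinal scale; missingness removes whole date blocks.
    """
    scale = config.scale
    if scale is None:
        raise ValueError("mode must be historical_1767 or historical_1789")
    rng = np.random.default_rng(config.seed)
    dates = _date_range(config)
    cycle = seasonal_cycle(dates, config.monthly_t_c)
    anom = _ar1(len(dates), config.phi, config.sigma, rng)
    t14 = cycle + anom
    t08 = t14 + config.morning_offset_c + rng.normal(0.0, 0.5, len(dates))
    winds14 = _wind_speeds(dates, config, rng)
    winds08 = _wind_speeds(dates, config, rng)
    missing = _missing_mask(len(dates), config, rng)
    q = config.fahrenheit_rounding

    def to_f(t_c: float) -> float:
        return round((t_c * 9.0 / 5.0 + 32.0) / q) * q

    records = []
    for i, d in enumerate(dates):
        if missing[i]:
            continue
        for hour, t_c, v in (("08:00", t08[i], winds08[i]),
                             ("14:00", t14[i], winds14[i])):
            records.append(ObservationRecord(
                date=d, hour_lt=hour,
                temperature=to_f(float(t_c)), temperature_unit="F",
                wind=float(discretize_wind(float(v), scale)),
                wind_kind="ordinal_force", wind_scale_id=scale.scale_id,
            ))
    return ObservationSeries(
        station_name=config.station_name, records=records,
        metadata={"synthetic": True, "config": config.model_dump()},
    )


def discretize_wind(v10: float, scale: WindScale) -> int:
    """Nearest-representative force code for a 10 m speed; ties go lower.

    Bin edges are midpoints between consecutive representative speeds, so
    each representative speed maps back to its own code.
    """
    if v10 < 0:
        raise ValueError(f"wind speed must be >= 0, got {v10}")
    codes = np.array(scale.codes)
    speeds = np.array([scale.mapping[c] for c in codes])
    edges = (speeds[:-1] + speeds[1:]) / 2.0
    return int(codes[np.searchsorted(edges, v10, side="left")])
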