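"""Monthly/seasonal aggregation, contemporary normals, anomalies, envelopes.

This is the comparison machinery between a short historical series and a
30-year contemporary reference: monthly summaries at a fixed observation
hour, equal-weight seasonal means, calendar-month and day-of-year normals
(mean, SD) from the contemporary record, historical-minus-normal anomalies,
exceedance of +-k*SD daily envelopes, and threshold frequencies such as the
percentage of days with WCT below 0 degC.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASONS",
    "NormalsTable",
    "monthly_stats",
    "seasonal_stats",
    "contemporary_normals",
    "anomalies",
    "envelope_exceedance",
    "percent_days_below",
    "build_report",
]

#: season definitions; Dec-Feb is assigned to the year of its January
SEASONS: dict[str, tuple[int, ...]] = {
    "Sep-Nov": (9, 10, 11),
    "Dec-Feb": (12, 1, 2),
    "Mar-May": (3, 4, 5),
    "Jun-Aug": (6, 7, 8),
    "Jan-Jun": (1, 2, 3, 4, 5, 6),
}

_DOY_REF_YEAR = 2000  # leap reference so every (month, day) has a stable slot


def _doy(date: dt.date) -> int:
    return dt.date(_DOY_REF_YEAR, date.month, date.day).timetuple().tm_yday


def _as_series(values) -> pd.Series:
    """Coerce dated values to a float Series indexed by datetime, sorted."""
    s = pd.Series(values) if not isinstance(values, pd.Series) else values
    s = s.copy()
    s.index = pd.DatetimeIndex(s.index)
    return s.astype(float).sort_index()


def monthly_stats(values, variable: str = "value",
                  min_coverage: float = 0.7) -> pd.DataFrame:
    """Per-(year, month) mean/min/max with coverage flag.

    ``values``: dated values at a fixed hour (Series indexed by date, or a
    mapping date -> value).  Months with any data are always emitted:
    ``partial`` marks months with any missing calendar day (the footnote
    convention of expedition climatologies), ``low_coverage`` those below
    ``min_coverage``; neither is dropped.
    """
    s = _as_series(values).dropna()
    rows = []
    for (year, month), sub in s.groupby([s.index.year, s.index.month]):
        ndays = pd.Period(f"{year}-{month:02d}").days_in_month
        coverage = len(sub) / ndays
        rows.append({
            "year": int(year), "month": int(month), "variable": variable,
            "mean": float(sub.mean()), "min": float(sub.min()),
            "max": float(sub.max()), "n_obs": int(len(sub)),
            "coverage": coverage, "partial": coverage < 1.0,
            "low_coverage": coverage < min_coverage,
        })
    return pd.DataFrame(rows, columns=["year", "month", "variable", "mean",
                                       "min", "max", "n_obs", "coverage",
                                       "partial", "low_coverage"])


def seasonal_stats(monthly: pd.DataFrame,
                   season_def: Mapping[str, Sequence[int]] = SEASONS
                   ) -> pd.DataFrame:
    """Equal-month-weight seasonal means from monthly summaries.

    Dec-Feb spans the year boundary and is assigned to the January year.
    A season-year missing any constituent month yields no row.
    """
    rows = []
    for variable, sub in monthly.groupby("variable"):
        lookup = {(int(r.year), int(r.month)): float(r["mean"])
                  for _, r in sub.iterrows()}
        years = sorted({y for y, _ in lookup})
        for season, months in season_def.items():
            for year in years:
                vals = []
                for m in months:
                    # months >= first listed month that exceed the season's
                    # January-anchored months belong to the previous year
                    y = year - 1 if (12 in months and m == 12) else year
                    if (y, m) not in lookup:
                        break
                    vals.append(lookup[(y, m)])
                else:
                    rows.append({"season": season, "year": year,
                                 "variable": variable,
                                 "mean": float(np.mean(vals)),
                                 "n_months": len(months)})
    return pd.DataFrame(rows, columns=["season", "year", "variable", "mean",
                                       "n_months"])


@dataclass
class NormalsTable:
    """Reference statistics from a multi-year contemporary series.

    ``monthly``: per calendar month (1-12) mean/sd/min/max across all
    observations.  ``daily``: per day-of-year (1-366, leap reference)
    mean/sd across years, optionally pooled over a centered circular window
    of ``window`` days (this doubles as the Feb-29 treatment).
    """

    monthly: pd.DataFrame
    daily: pd.DataFrame
    reference_period: str = ""
    window: int = 15

    def monthly_mean(self, month: int) -> float:
        row = self.monthly.loc[self.monthly["month"] == month]
        if row.empty:
            raise KeyError(f"month {month} absent from normals")
        return float(row["mean"].iloc[0])


def contemporary_normals(values, window: int = 15,
                         reference_period: str = "") -> NormalsTable:
    """Calendar-month and day-of-year normals from a multi-year series.

    Requires at least two distinct years (SD is undefined otherwise).  The
    day-of-year statistics pool observations within a centered circular
    window (default 15 days) across all years, which smooths the envelope
    and gives Feb 29 a populated slot.
    """
    s = _as_series(values).dropna()
    years = s.index.year.unique()
    if len(years) < 2:
        raise ValueError(
            f"normals need >= 2 distinct years, got {len(years)}")
    monthly = (
        s.groupby(s.index.month)
        .agg(["mean", "std", "min", "max", "count"])
        .rename(columns={"std": "sd", "count": "n_obs"})
        .rename_axis("month").reset_index()
    )
    # circular windowed day-of-year moments via binned sums
    doy = np.array([_doy(d) for d in s.index.date])
    n_bins = 366
    cnt = np.bincount(doy - 1, minlength=n_bins).astype(float)
    s1 = np.bincount(doy - 1, weights=s.to_numpy(), minlength=n_bins)
    s2 = np.bincount(doy - 1, weights=s.to_numpy() ** 2, minlength=n_bins)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    kernel = np.ones(window)

    def circ(x: np.ndarray) -> np.ndarray:
        if half == 0:
            return x.copy()
        ext = np.concatenate([x[-half:], x, x[:half]])
        return np.convolve(ext, kernel, mode="valid")

    wc, w1, w2 = circ(cnt), circ(s1), circ(s2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(wc > 0, w1 / np.maximum(wc, 1), np.nan)
        var = np.where(wc > 1, (w2 - w1 ** 2 / np.maximum(wc, 1))
                       / np.maximum(wc - 1, 1), np.nan)
    sd = np.sqrt(np.clip(var, 0.0, None))
    daily = pd.DataFrame({"doy": np.arange(1, n_bins + 1), "mean": mean,
                          "sd": sd, "n_obs": wc.astype(int)})
    return NormalsTable(monthly=monthly, daily=daily,
                        reference_period=reference_period, window=window)


def anomalies(historical_monthly: pd.DataFrame,
              normals: NormalsTable) -> pd.DataFrame:
    """Historical monthly mean minus contemporary monthly normal.

    Defined only for (year, month) cells whose calendar month exists in the
    normals; others are omitted.
    """
    ref = dict(zip(normals.monthly["month"].astype(int),
                   normals.monthly["mean"].astype(float)))
    rows = []
    for _, r in historical_monthly.iterrows():
        m = int(r["month"])
        if m not in ref:
            continue
        rows.append({
            "year": int(r["year"]), "month": m, "variable": r["variable"],
            "historical_mean": float(r["mean"]), "normal": ref[m],
            "anomaly": float(r["mean"]) - ref[m],
        })
    return pd.DataFrame(rows, columns=["year", "month", "variable",
                                       "historical_mean", "normal", "anomaly"])


def envelope_exceedance(daily_values, normals: NormalsTable,
                        k: float = 2.0) -> pd.DataFrame:
    """Days whose value lies strictly beyond mean +- k*SD for their calendar day.

    Returns per-month rows plus a total row ("month" = 0) with the count of
    evaluated days, the count exceeding, and the exceedance fraction.
    """
    s = _as_series(daily_values).dropna()
    daily = normals.daily.set_index("doy")
    doy = np.array([_doy(d) for d in s.index.date])
    mean = daily["mean"].to_numpy()[doy - 1]
    sd = daily["sd"].to_numpy()[doy - 1]
    ok = np.isfinite(mean) & np.isfinite(sd)
    exceed = ok & (np.abs(s.to_numpy() - mean) > k * sd)
    df = pd.DataFrame({"month": s.index.month, "ok": ok, "exceed": exceed})
    rows = []
    for month, sub in df.groupby("month"):
        n = int(sub["ok"].sum())
        x = int(sub["exceed"].sum())
        rows.append({"month": int(month), "n_days": n, "n_exceed": x,
                     "fraction": x / n if n else np.nan})
    n_tot = int(df["ok"].sum())
    x_tot = int(df["exceed"].sum())
    rows.append({"month": 0, "n_days": n_tot, "n_exceed": x_tot,
                 "fraction": x_tot / n_tot if n_tot else np.nan})
    return pd.DataFrame(rows, columns=["month", "n_days", "n_exceed",
                                       "fraction"])


def percent_days_below(values, threshold: float) -> float:
    """Percent of non-missing days strictly below ``threshold``."""
    s = _as_series(values).dropna()
    if s.empty:
        raise ValueError("no non-missing values")
    return 100.0 * float((s < threshold).mean())


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Named tabular fragments plus provenance, serialized deterministically."""

    fragments: dict[str, pd.DataFrame] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def build_report(fragments: Mapping[str, pd.DataFrame], out_dir,
                 provenance: Optional[dict] = None) -> ComparisonReport:
    """Write each fragment as CSV plus a JSON index with provenance.

    Every CSV carries a provenance comment header (config hash); rerunning
    on identical inputs is byte-identical.  Returns the assembled report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = dict(provenance or {})
    blob = json.dumps({k: _frame_digest(v) for k, v in sorted(fragments.items())},
                      sort_keys=True) + json.dumps(prov, sort_keys=True, default=str)
    prov["content_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    index = {"provenance": prov, "tables": {}}
    for name in sorted(fragments):
        frame = fragments[name]
        path = out / f"{name}.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(f"# provenance: {prov['content_hash']}\n")
            frame.to_csv(fh, index=False, lineterminator="\n",
                         float_format="%.10g")
        index["tables"][name] = {"path": path.name, "n_rows": int(len(frame)),
                                 "columns": list(map(str, frame.columns))}
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(index, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return ComparisonReport(fragments=dict(fragments), provenance=prov)


def _frame_digest(frame: pd.DataFrame) -> str:
    return hashlib.sha256(
        frame.to_csv(index=False, float_format="%.10g").encode()
    ).hexdigest()
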