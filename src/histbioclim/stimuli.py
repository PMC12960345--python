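"""Interdiurnal temperature change and thermal-stimulus classification.

The stimulating effect of the thermal environment is graded from the
absolute day-to-day change of air temperature at a fixed observation hour
(Bajbakova-style bands): <= 2.0 degC neutral, 2.1-4.0 perceptible,
4.1-6.0 significant, >= 6.1 severe.  Changes are rounded to 0.1 degC
(half away from zero) before classification so the printed bands tile the
line without gaps.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import pandas as pd

from .conversions import StandardObservation

__all__ = [
    "StimulusRecord",
    "STIMULUS_LABELS",
    "interdiurnal_changes",
    "stimulus_category",
    "stimulus_frequencies",
]

STIMULUS_LABELS = ("neutral", "perceptible", "significant", "severe")


@dataclass(frozen=True)
class StimulusRecord:
    """Absolute temperature change from the previous calendar day.

    ``date`` is the later day of the pair; ``delta_t`` >= 0 in degC.
    """

    date: dt.date
    delta_t: float
    category: str


def _round_half_away(x: float, decimals: int = 1) -> float:
    q = 10 ** decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def stimulus_category(delta_t: float) -> str:
    """Stimulus band for an absolute interdiurnal change (degC, >= 0)."""
    if delta_t < 0:
        raise ValueError(f"interdiurnal change must be >= 0, got {delta_t}")
    r = _round_half_away(delta_t)
    if r <= 2.0:
        return "neutral"
    if r <= 4.0:
        return "perceptible"
    if r <= 6.0:
        return "significant"
    return "severe"


def interdiurnal_changes(obs: Sequence[StandardObservation],
                         hour: str) -> list[StimulusRecord]:
    """Day-to-day |dT| at a fixed hour, for consecutive calendar days only.

    A pair contributes iff both days carry a temperature at ``hour``; any
    calendar gap produces no record.
    """
    temps: dict[dt.date, float] = {}
    for o in obs:
        if o.hour_lt == hour and o.t_c is not None:
            temps[o.date] = o.t_c
    out: list[StimulusRecord] = []
    for day in sorted(temps):
        prev = day - dt.timedelta(days=1)
        if prev in temps:
            delta = abs(temps[day] - temps[prev])
            out.append(StimulusRecord(day, delta, stimulus_category(delta)))
    return out


def stimulus_frequencies(
    records: Sequence[StimulusRecord],
    grouping: Literal["month", "year", "period"] = "period",
) -> pd.DataFrame:
    """Per-group category percentages (tidy: group, category, percent, n).

    Percentages are over the records present in each group and sum to 100;
    empty groups are simply absent.  ``n`` is the group's record count.
    """
    if not records:
        return pd.DataFrame(columns=["group", "category", "percent", "n"])
    df = pd.DataFrame({
        "date": [r.date for r in records],
        "category": pd.Categorical([r.category for r in records],
                                   categories=list(STIMULUS_LABELS)),
    })
    if grouping == "month":
        df["group"] = [f"{d.year:04d}-{d.month:02d}" for d in df["date"]]
    elif grouping == "year":
        df["group"] = [f"{d.year:04d}" for d in df["date"]]
    elif grouping == "period":
        df["group"] = "all"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    rows = []
    for g, sub in df.groupby("group", sort=True, observed=True):
        n = len(sub)
        counts = sub["category"].value_counts(sort=False)
        for cat in STIMULUS_LABELS:
            rows.append({
                "group": g,
                "category": cat,
                "percent": 100.0 * counts.get(cat, 0) / n,
                "n": n,
            })
    return pd.DataFrame(rows)
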