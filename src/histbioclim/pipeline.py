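"""End-to-end orchestration: standardize -> indices -> stimuli -> climatology.

Stages chain through documented CSV schemas (no hidden state), so each can
be run and tested independently; ``run_full`` executes the whole comparison
of a historical register against a contemporary reference series and writes
a deterministic report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel

from . import bioindices, climatology, stimuli
from .conversions import StandardObservation, standardize
from .registers import RegisterSchema, read_register
from .climatology import ComparisonReport

__all__ = [
    "RunConfig",
    "load_schema",
    "standardized_frame",
    "bio_frame",
    "load_standardized",
    "run_full",
]

log = logging.getLogger("histbioclim")


class RunConfig(BaseModel):
    """Configuration of a full historical-vs-contemporary run."""

    historical_register: Path
    historical_schema: Path
    contemporary_register: Path
    contemporary_schema: Path
    out_dir: Path
    historical_hour: str = "14:00"
    contemporary_hour: str = "15:00"
    normals_window: int = 15
    min_coverage: float = 0.7
    envelope_k: Sequence[float] = (1.0, 2.0)
    seed: Optional[int] = None

    def digest(self) -> str:
        # out_dir is where the report lands, not part of its content
        payload = self.model_dump_json(exclude={"out_dir"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_schema(path) -> RegisterSchema:
    """Load a register schema sidecar from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    return RegisterSchema(**data)


# ---------------------------------------------------------------------------
# frame <-> object adapters (the stage CSV schemas)
# ---------------------------------------------------------------------------

def standardized_frame(obs: Sequence[StandardObservation]) -> pd.DataFrame:
    """Tidy standardized observations: date, hour, t_c, v10, v12."""
    return pd.DataFrame({
        "date": [o.date.isoformat() for o in obs],
        "hour": [o.hour_lt for o in obs],
        "t_c": [o.t_c for o in obs],
        "v10": [o.v10 for o in obs],
        "v12": [o.v12 for o in obs],
    })


def load_standardized(path) -> list[StandardObservation]:
    """Read a standardized-stage CSV back into observations."""
    import datetime as dt

    df = pd.read_csv(path, comment="#")
    for col in ("date", "hour", "t_c", "v10", "v12"):
        if col not in df.columns:
            raise ValueError(f"standardized CSV missing column {col!r}")
    out = []
    for _, r in df.iterrows():
        out.append(StandardObservation(
            date=dt.date.fromisoformat(str(r["date"])),
            hour_lt=str(r["hour"]),
            t_c=None if pd.isna(r["t_c"]) else float(r["t_c"]),
            v10=None if pd.isna(r["v10"]) else float(r["v10"]),
            v12=None if pd.isna(r["v12"]) else float(r["v12"]),
        ))
    return out


def bio_frame(records: Sequence[bioindices.BioRecord]) -> pd.DataFrame:
    """Tidy index records, one row per observation."""
    return pd.DataFrame({
        "date": [r.date.isoformat() for r in records],
        "hour": [r.hour_lt for r in records],
        "wct": [r.wct for r in records],
        "iclp_move": [r.iclp_move for r in records],
        "iclp_stand": [r.iclp_stand for r in records],
        "frostbite": [r.frostbite for r in records],
        "clothing": [r.clothing for r in records],
        "wct_valid": [r.wct_valid for r in records],
    })


def _hour_series(obs: Sequence[StandardObservation], hour: str,
                 attr: str) -> dict:
    return {o.date.isoformat(): getattr(o, attr)
            for o in obs if o.hour_lt == hour and getattr(o, attr) is not None}


def _bio_hour_series(records, hour: str, attr: str) -> dict:
    return {r.date.isoformat(): getattr(r, attr)
            for r in records if r.hour_lt == hour and getattr(r, attr) is not None}


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_full(config: RunConfig) -> ComparisonReport:
    """Run the whole comparison and write its report to ``config.out_dir``.

    Outputs (CSV + report.json): monthly and seasonal summaries for both
    periods, monthly anomalies (historical minus contemporary normal),
    stimulus frequency tables, envelope exceedances of historical daily WCT
    against the contemporary day-of-year normals, and threshold
    frequencies (percent of days with WCT below 0 degC).
    """
    log.info("standardizing registers (wind profile exponent 0.2, "
             "WCT wind at 10 m, Iclp wind at 1.2 m)")
    hist_schema = load_schema(config.historical_schema)
    cont_schema = load_schema(config.contemporary_schema)
    hist = read_register(config.historical_register, hist_schema)
    cont = read_register(config.contemporary_register, cont_schema)
    hist_std = standardize(hist)
    cont_std = standardize(cont)
    hist_bio = bioindices.compute_bio_series(hist_std)
    cont_bio = bioindices.compute_bio_series(cont_std)

    fragments: dict[str, pd.DataFrame] = {}
    hh, ch = config.historical_hour, config.contemporary_hour

    monthly_parts, seasonal_parts, anomaly_parts = [], [], []
    cont_normals = {}
    for var, hist_map, cont_map in (
        ("t", _hour_series(hist_std, hh, "t_c"), _hour_series(cont_std, ch, "t_c")),
        ("v12", _hour_series(hist_std, hh, "v12"), _hour_series(cont_std, ch, "v12")),
        ("wct", _bio_hour_series(hist_bio, hh, "wct"), _bio_hour_series(cont_bio, ch, "wct")),
        ("iclp_move", _bio_hour_series(hist_bio, hh, "iclp_move"),
         _bio_hour_series(cont_bio, ch, "iclp_move")),
        ("iclp_stand", _bio_hour_series(hist_bio, hh, "iclp_stand"),
         _bio_hour_series(cont_bio, ch, "iclp_stand")),
    ):
        hist_monthly = climatology.monthly_stats(hist_map, var, config.min_coverage)
        cont_monthly = climatology.monthly_stats(cont_map, var, config.min_coverage)
        monthly_parts.append(hist_monthly.assign(period="historical"))
        monthly_parts.append(cont_monthly.assign(period="contemporary"))
        seasonal_parts.append(
            climatology.seasonal_stats(hist_monthly).assign(period="historical"))
        seasonal_parts.append(
            climatology.seasonal_stats(cont_monthly).assign(period="contemporary"))
        if cont_map:
            normals = climatology.contemporary_normals(
                cont_map, window=config.normals_window)
            cont_normals[var] = normals
            anomaly_parts.append(climatology.anomalies(hist_monthly, normals))
    fragments["monthly"] = pd.concat(monthly_parts, ignore_index=True)
    fragments["seasonal"] = pd.concat(seasonal_parts, ignore_index=True)
    fragments["anomalies"] = pd.concat(anomaly_parts, ignore_index=True)

    hist_stim = stimuli.interdiurnal_changes(hist_std, hh)
    cont_stim = stimuli.interdiurnal_changes(cont_std, ch)
    fragments["stimuli_monthly"] = pd.concat([
        stimuli.stimulus_frequencies(hist_stim, "month").assign(period="historical"),
        stimuli.stimulus_frequencies(cont_stim, "month").assign(period="contemporary"),
    ], ignore_index=True)
    fragments["stimuli_annual"] = pd.concat([
        stimuli.stimulus_frequencies(hist_stim, "period").assign(period="historical"),
        stimuli.stimulus_frequencies(cont_stim, "period").assign(period="contemporary"),
    ], ignore_index=True)

    env_parts = []
    hist_wct = _bio_hour_series(hist_bio, hh, "wct")
    if "wct" in cont_normals and hist_wct:
        for k in config.envelope_k:
            env = climatology.envelope_exceedance(hist_wct, cont_normals["wct"], k)
            env_parts.append(env.assign(k=k, variable="wct"))
    if env_parts:
        fragments["envelope_exceedance"] = pd.concat(env_parts, ignore_index=True)

    thresh_rows = []
    for label, mapping in (("historical", hist_wct),
                           ("contemporary", _bio_hour_series(cont_bio, ch, "wct"))):
        if mapping:
            thresh_rows.append({
                "period": label, "variable": "wct", "threshold": 0.0,
                "percent_days_below": climatology.percent_days_below(mapping, 0.0),
                "n_days": len(mapping),
            })
    fragments["threshold_frequencies"] = pd.DataFrame(thresh_rows)

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "historical_scale": hist_schema.wind_scale_id,
        "conventions": {
            "wind_profile_exponent": 0.2,
            "wct_wind_height_m": 10.0,
            "iclp_wind_height_m": 1.2,
        },
    }
    report = climatology.build_report(fragments, config.out_dir, provenance)
    log.info("report written to %s", config.out_dir)
    return report
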