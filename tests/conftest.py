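import datetime as dt

import pytest

from histbioclim.registers import ObservationRecord, ObservationSeries


@pytest.fixture
def make_register_csv(tmp_path):
    """Write a small register CSV and return its path."""

    def _write(rows, header="date,hour,temp,wind", name="reg.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
        return path

    return _write


@pytest.fixture
def historical_series():
    """Three-day 1767-style register (degF, ordinal force codes)."""
    records = []
    for i, (t_f, force) in enumerate([(30.0, 1), (32.0, 2), (34.0, 3)]):
        records.append(ObservationRecord(
            date=dt.date(1767, 12, 10) + dt.timedelta(days=i),
            hour_lt="14:00",
            temperature=t_f, temperature_unit="F",
            wind=float(force), wind_kind="ordinal_force",
            wind_scale_id="scale_1767",
        ))
    return ObservationSeries(station_name="fixture", records=records)
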