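"""Read an 18th-century-style register and standardize it.

The register stores Fahrenheit temperatures and ordinal wind-force codes
(here the six-point 1767-68 scale); standardization converts to degC and
to wind speeds at 10 m and 1.2 m, then the biometeorological indices are
computed per observation.
"""

import tempfile
from pathlib import Path

from histbioclim import (RegisterSchema, compute_bio_series, read_register,
                         standardize, validate_series)

csv_text = """date,hour,temp,wind
1767-12-10,14:00,30,1
1767-12-11,14:00,21,3
1767-12-12,14:00,-4,5
1767-12-13,14:00,NA,2
"""

path = Path(tempfile.mkdtemp()) / "register.csv"
path.write_text(csv_text)

schema = RegisterSchema(station_name="Neu-Herrnhut style", temperature_unit="F",
                        wind_kind="ordinal_force", wind_scale_id="scale_1767")
series = read_register(path, schema)
print(f"read {len(series)} records; issues: {validate_series(series) or 'none'}")

for obs, bio in zip(standardize(series), compute_bio_series(standardize(series))):
    if bio.wct is None:
        t_str = "   NA " if obs.t_c is None else f"{obs.t_c:+6.1f}"
        print(f"{obs.date}  t={t_str} degC  "
              f"-> indices skipped ({bio.missing_reason})")
        continue
    print(f"{obs.date}  t={obs.t_c:+6.1f} degC  v10={obs.v10:5.2f} m/s  "
          f"WCT={bio.wct:+6.1f} degC  Iclp={bio.iclp_move:4.2f} clo  "
          f"[{bio.frostbite} frostbite risk, {bio.clothing}]")

# Force 5 on this scale stands for 20.75 m/s at 10 m: at -20 degC that
# drives the wind chill toward -33 degC even though the air itself is far
# milder, which is why the register's wind codes matter as much as its
# thermometer readings.
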