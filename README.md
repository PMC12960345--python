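# histbioclim

Cold-climate biometeorology for rescued historical weather registers.

Early-instrumental registers from Arctic mission and expedition stations —
twice-daily readings of air temperature in degrees Fahrenheit and visual
wind-force estimates on station-specific ordinal scales — can be compared
against a modern 30-year station record once both are brought onto a common
footing. `histbioclim` does that end to end for practitioners in historical
climatology and human biometeorology:

1. **Registers** — typed readers/writers and validation for register CSVs
   with a declared schema (units, wind representation, missing token);
   transcription quirks such as non-ASCII minus signs are normalized.
2. **Conversions** — °F→°C; ordinal force code → representative wind speed
   at 10 m via the register's scale table; height adjustment with the
   power-law profile *v(h₂) = v(h₁)·(h₂/h₁)^0.2*.
3. **Bioindices** — wind chill temperature (WCT) and insulation predicted
   (Iclp), with frostbite-risk and clothing-demand classification:

   WCT = 13.12 + 0.6215·t − 11.37·v₁₀^0.16 + 0.3965·t·v₁₀^0.16  [°C, v₁₀ in m·s⁻¹ at 10 m]

   Iclp = 0.082·(91.4 − (1.8·t + 32)) / (0.01724·M) − 1/(0.61 + (1.9·v)^0.5)  [clo, v at 1.2 m]

   with M the metabolic rate (135 W·m⁻² walking at 4 km·h⁻¹, 70 W·m⁻²
   standing) and 1 clo = 0.155 K·m⁻²·W⁻¹.
4. **Stimuli** — interdiurnal temperature changes at a fixed observation
   hour, classified as neutral (≤ 2.0 °C), perceptible (2.1–4.0),
   significant (4.1–6.0) or severe (≥ 6.1), with frequency tables.
5. **Climatology** — monthly/seasonal summaries, calendar-month and
   day-of-year normals (mean, SD) from the contemporary record, historical
   minus contemporary anomalies, ±k·SD envelope exceedance, threshold
   frequencies.
6. **Synthetic data** — a seeded generator (seasonal cycle + AR(1) daily
   anomalies + per-month Weibull winds, discretized to the ordinal scales
   in historical mode) so the full pipeline is testable without archival
   data, which survives only in manuscripts.

## Worked example

```python
from histbioclim import adjust_wind_height, wct, iclp, frostbite_category

t, v12 = -25.2, 6.1                      # degC, m/s measured at 1.2 m
v10 = adjust_wind_height(v12, 1.2, 10)   # 9.32 m/s at 10 m
print(round(wct(t, v10), 1))             # -33.1  (degC)
print(frostbite_category(wct(t, v10)))   # very high
print(round(iclp(t, v12, 135), 2))       # 3.44  (clo, walking)
print(round(iclp(t, v12, 70), 2))        # 6.87  (clo, standing)
```

A WCT of −33.1 °C means exposed skin can freeze within tens of minutes;
the standing-person clothing demand of ~6.9 clo calls for heavy arctic
clothing. The `examples/` directory has one short script per capability
(extreme-day indices, register standardization, stimulus classification,
and a full synthetic comparison run), each printing and explaining its
numbers. A thin CLI mirrors the pipeline stages:

```bash
histbioclim simulate reg.csv --mode historical_1789 --seed 1 --years 1 --start-year 1789
histbioclim standardize reg.csv reg.schema.yaml std.csv
histbioclim indices std.csv bio.csv
histbioclim run --config run.yaml --seed 1 --out report/
```

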