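# Methods

## The problem

Pre-1890 Arctic weather registers record air temperature in °F and wind as
an ordinal force code judged by eye against sea state. To ask whether an
18th-century winter *felt* colder than today's, both the historical register
and a contemporary 30-year station record must be standardized to common
units, converted into biometeorological indices that depend only on
temperature and wind (the only variables the registers carry), and compared
through monthly statistics, anomalies and daily variability envelopes. This
package implements that pipeline; each stage is a pure function over typed
records, chained by the orchestration layer through documented CSV schemas.

## Standardization

* **Temperature**: t(°C) = (t(°F) − 32)·5/9. Readings are accepted in
  [−80, +60] °C after conversion; values outside are flagged, not silently
  altered.
* **Ordinal wind**: each register scale ships as a data table mapping force
  code to a representative speed valid at 10 m (six-point 1767-style scale:
  1→0.45, 2→3.4, 3→8.0, 4→13.9, 5→20.75, 6→30.5 m·s⁻¹; five-point
  1789-style scale: 0→0.3, 1→2.4, 2→9.3, 3→18.9, 4→30.5 m·s⁻¹). The
  historical two-step derivation (station scale → Beaufort → speed) is
  collapsed into these end-to-end tables, which are the operative numbers.
  The six-point scale has no calm code; force 0 on it is rejected as out of
  domain rather than silently mapped to 0 m·s⁻¹ (user-defined scales can
  add a calm code).
* **Height adjustment**: v(h₂) = v(h₁)·(h₂/h₁)^α with α = 0.2 (exposed
  coastal terrain; α is configurable for sensitivity work). Contemporary
  anemometer height defaults to the WMO-standard 10 m when a register's
  metadata does not state it.

Wind enters the two indices at different heights, a convention that
matters numerically: WCT takes the 10 m speed, Iclp the 1.2 m
(chest-height) speed. With these conventions the two extreme afternoons in
the validation set reproduce to ≤ 0.1 °C; alternative conventions (km·h⁻¹,
unadjusted winds) do not.

## Indices

**WCT** (°C): 13.12 + 0.6215·t − 11.37·v₁₀^0.16 + 0.3965·t·v₁₀^0.16.
Monotonically increasing in t, decreasing in v for t < 28 °C; at v₁₀ = 1
m·s⁻¹ it collapses to the affine closed form 1.75 + 1.018·t, which the
tests use as an exact anchor. The formula's conventional validity domain is
t ≤ 10 °C and v₁₀ ≥ 1.34 m·s⁻¹; outside it the value is still computed but
flagged, because year-round series are routinely summarized (summer WCT
means are meaningful as "no frostbite risk", not as skin-freezing times).
Zero or negative v₁₀ is a domain error.

**Iclp** (clo): 0.082·(91.4 − (1.8·t + 32))/(0.01724·M) − 1/(0.61 + (1.9·v)^0.5).
The first term is the total insulation required for heat balance at
metabolic rate M, the second the insulation of the near-surface air layer;
their difference is what clothing must supply. The difference
Iclp(70) − Iclp(135) is independent of wind (the air layer cancels), which
the tests exploit as an identity.

**Frostbite categories** (from WCT, all thresholds configurable):
lack (> 0 °C), low (0…−10], moderate (−10…−25], high (−25…−30],
very high (≤ −30 °C, exposed skin can freeze in 10–30 min). A 4-level
variant merges *very high* into *high* for figure-legend compatibility.
The −30 °C very-high threshold follows the operational skin-freezing-time
bands; category boundaries are upper-inclusive so printed monthly means
like −10.5 °C fall in the moderate class.

**Clothing bands** (from moving-person Iclp): < 0.5 very light summer;
0.5–1.0 light summer; 1.0–1.5 summer with accessories; 1.5–2.5
spring/autumn; 2.5–3.0 spring/autumn with increased insulation; 3.0–4.0
normal winter; > 4.0 heavy winter ("arctic") clothing.

Known residual: published per-day Iclp extremes computed with the BioKlima
package differ from direct evaluation of the printed formula by
0.02–0.07 clo under every wind-height/unit convention we tested (e.g. 3.44
vs 3.51 clo for the coldest historical afternoon). We evaluate the formula
as printed and do not tune constants to absorb the difference; WCT is
unaffected.

## Interdiurnal stimuli

The stimulus classification grades |t(day) − t(day−1)| at a fixed
observation hour (14:00 LT historical, 15:00 LT contemporary): ≤ 2.0 °C
neutral, 2.1–4.0 perceptible, 4.1–6.0 significant, ≥ 6.1 severe. Changes
are rounded to 0.1 °C half-away-from-zero before classification so the
bands tile the line (2.04 → neutral, 2.05 → perceptible). Only consecutive
calendar days both observed at the stated hour form a pair; gaps produce
no record, and frequency tables report the pair count n alongside the
percentages so the denominator is explicit. Absolute (unsigned) change is
used: the bands grade magnitude, and a 9 °C overnight warming is as
physiologically loaded as a cooling.

## Climatology and comparison

* **Monthly statistics** are arithmetic mean/min/max over available days at
  the fixed afternoon hour. Months with any missing day carry a `partial`
  flag (the footnote convention of expedition tables); months below the
  `min_coverage` fraction (default 0.7) additionally carry `low_coverage`.
  Nothing is dropped — a 22-day July is still a July.
* **Seasonal means** weight constituent months equally (mean of monthly
  means, the climate-normals convention) rather than pooling days;
  Dec–Feb is assigned to the year of its January; a season missing any
  month is omitted rather than computed from a ragged subset.
* **Normals** from the contemporary series: per calendar month
  (mean/SD/min/max pooled over all observations) and per day-of-year
  (mean/SD across years). Day-of-year statistics pool a centered circular
  window (default 15 days, configurable including off), which smooths the
  envelope and gives Feb 29 a populated slot; day-of-year indexing uses a
  leap-year reference so every (month, day) has a stable slot. Fewer than
  two distinct years is an error (SD undefined).
* **Anomalies** are historical monthly mean minus the contemporary monthly
  normal, per (year, month), defined only where both exist.
* **Envelope exceedance** flags days with |x − mean_doy| > k·SD_doy
  (strict inequality, so a value exactly on the envelope does not exceed
  it). Under the generator's Gaussian model the k = 2 self-exceedance rate
  converges to 2·(1 − Φ(2)) ≈ 4.55 %, which the tests use as a
  calibration check; windowed SD estimation and serial correlation push
  the finite-sample value slightly below that.
* **Threshold frequencies** (e.g. percent of days with WCT < 0 °C) use
  strict inequality over non-missing days.
* **Reports** serialize deterministically (sorted tables, fixed float
  format, provenance hash excluding the output path), so identical inputs
  give byte-identical outputs wherever they are written.

## Synthetic study conditions

The archival daily series is unpublished, so the generator defines the
study conditions under which the pipeline is exercised and calibrated:

* **Seasonal cycle**: monthly afternoon-temperature targets anchored at
  mid-month and interpolated periodically. Defaults emulate a Nuuk-like
  coastal-Arctic 15:00 LT climatology (Jan −7.6, Feb −8.2, Mar −7.4,
  Apr −2.6, May 2.3, Jun 6.3, Jul 8.9, Aug 8.2, Sep 3.9, Oct 0.1,
  Nov −3.2, Dec −5.3 °C).
* **Daily anomalies**: stationary AR(1) with φ = 0.7 and innovation SD
  σ = 2.5 °C (marginal SD ≈ 3.5 °C) — the minimal serially-correlated
  model producing realistic interdiurnal-change distributions, the
  quantity the stimulus module classifies. A Gaussian AR(1) reproduces the
  observed predominance of neutral stimuli (~54 % vs ~53 % reported for
  this climate) but, lacking heavy tails, undershoots severe-stimulus
  frequency (~3 % vs ~8 %); conclusions about severe-tail frequencies on
  real data therefore do not follow from these tests.
* **Wind**: per-month Weibull at 10 m (shape 2, scale set so the mean hits
  the monthly target, defaults from a Nuuk-like 1.2 m climatology moved to
  10 m); temperature–wind dependence beyond shared monthly seasonality is
  not modelled.
* **Historical mode**: twice-daily records (08:00 with a −1.5 °C offset,
  14:00), °F rounded to 0.5 °F (plausible manuscript precision,
  configurable), winds discretized to the mode's ordinal scale by nearest
  representative speed with midpoint bin edges and ties to the lower code,
  and missingness as contiguous date blocks (voyages, gaps) rather than
  i.i.d. dropout.
* **Determinism**: one `numpy` generator seeded from the config; same seed
  gives byte-identical registers.

What passing tests show: unit/height/scale conversions are exact; the
index formulas match an independent arbitrary-precision oracle to 1e−9;
the aggregation machinery recovers generator truth (monthly means within
2·SE of the cycle's monthly mean on 30 simulated years; k = 2 envelope
exceedance within 1.5 percentage points of the Gaussian rate). What they
do not show: fidelity to the actual archival sequences, homogeneity of the
real contemporary record, or severe-stimulus rates under real
heavy-tailed weather.

## Problem sizes

The test suite and acceptance script use a 30-year contemporary series
(~11 000 daily records) and 1–4-year historical registers (~700–2 900
twice-daily records), the sizes the comparison itself is designed around;
the whole suite runs in well under a minute.

## Limitations

Station moves within the historical period are treated as one series; no
stability-dependent wind profiles (log/Monin–Obukhov) or gust modelling;
no radiation- or humidity-dependent indices (the registers only support
temperature + wind); figure rendering is out of scope (envelope and
frequency tables are emitted plot-ready).
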