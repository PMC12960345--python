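"""Classify interdiurnal temperature changes as thermal stimuli.

Day-to-day changes of the afternoon temperature are graded into
neutral / perceptible / significant / severe bands; a rapid winter warming
episode produces back-to-back severe stimuli.
"""

import datetime as dt

from histbioclim import interdiurnal_changes, stimulus_frequencies
from histbioclim.conversions import StandardObservation

# a February warming burst: -27.4 -> -18.0 -> -5.6 degC in two days,
# followed by a quieter week
temps = [-27.4, -18.0, -5.6, -7.0, -6.1, -8.3, -7.9, -9.0]
obs = [StandardObservation(dt.date(1791, 2, 10) + dt.timedelta(days=i),
                           "14:00", t_c=t, v10=None, v12=None)
       for i, t in enumerate(temps)]

records = interdiurnal_changes(obs, "14:00")
for r in records:
    print(f"{r.date}  |dT| = {r.delta_t:4.1f} degC  -> {r.category}")

print()
print(stimulus_frequencies(records, "month").to_string(index=False))

# The two severe stimuli (9.4 and 12.4 degC) are the kind of weather swing
# that is physiologically distressing; the frequency table shows their
# share of all classified day pairs in the month.
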