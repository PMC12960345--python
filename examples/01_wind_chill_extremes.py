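"""Wind chill on the two coldest recorded afternoons.

A wind speed observed (or inferred from an ordinal force code) near chest
height is moved to the 10 m reference height with the 0.2-power profile,
then fed to the wind-chill formula together with the air temperature.
"""

from histbioclim import adjust_wind_height, frostbite_category, iclp, wct

for label, t_c, v12 in [
    ("historical (23 Jan 1791 conditions)", -25.2, 6.1),
    ("contemporary (3 Mar 1997 conditions)", -25.9, 7.4),
]:
    v10 = adjust_wind_height(v12, 1.2, 10.0)
    w = wct(t_c, v10)
    print(f"{label}: t = {t_c} degC, wind {v12} m/s at 1.2 m "
          f"-> {v10:.2f} m/s at 10 m")
    print(f"  WCT = {w:.1f} degC  (frostbite risk: {frostbite_category(w)})")
    print(f"  Iclp moving   = {iclp(t_c, v12, 135):.2f} clo")
    print(f"  Iclp standing = {iclp(t_c, v12, 70):.2f} clo")

# WCT near -33/-35 degC means exposed skin can freeze within tens of
# minutes; the standing-person clothing demand (~7 clo) is heavy arctic
# clothing, roughly double the demand of a person walking at 4 km/h.
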