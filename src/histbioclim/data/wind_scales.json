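{
  "scales": [
    {
      "scale_id": "scale_1767",
      "aliases": ["scale_1767_6pt", "1767"],
      "description": "Six-point ordinal sea wind-force scale used in the 1767-68 register; representative speeds in m/s at 10 m.",
      "mapping": {"1": 0.45, "2": 3.4, "3": 8.0, "4": 13.9, "5": 20.75, "6": 30.5}
    },
    {
      "scale_id": "scale_1789",
      "aliases": ["scale_1789_5pt", "1789"],
      "description": "Five-point ordinal sea wind-force scale used in the 1789-92 register; representative speeds in m/s at 10 m.",
      "mapping": {"0": 0.3, "1": 2.4, "2": 9.3, "3": 18.9, "4": 30.5}
    }
  ],
  "version": "1.0"
}
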