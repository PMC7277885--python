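# Royal College of Physicians NEWS (2012) parameter bands.
# Intervals are closed on both printed endpoints; `min`/`max` omitted means
# open towards the physiologic sanity bound. Values are compared after
# rounding temperature to 0.1 degC and the other parameters to integers.
parameters:
  respiration_rate:
    - {max: 8, score: 3}
    - {min: 9, max: 11, score: 1}
    - {min: 12, max: 20, score: 0}
    - {min: 21, max: 24, score: 2}
    - {min: 25, score: 3}
  spo2:
    - {max: 91, score: 3}
    - {min: 92, max: 93, score: 2}
    - {min: 94, max: 95, score: 1}
    - {min: 96, score: 0}
  temperature:
    - {max: 35.0, score: 3}
    - {min: 35.1, max: 36.0, score: 1}
    - {min: 36.1, max: 38.0, score: 0}
    - {min: 38.1, max: 39.0, score: 1}
    - {min: 39.1, score: 2}
  systolic_bp:
    - {max: 90, score: 3}
    - {min: 91, max: 100, score: 2}
    - {min: 101, max: 110, score: 1}
    - {min: 111, max: 219, score: 0}
    - {min: 220, score: 3}
  heart_rate:
    - {max: 40, score: 3}
    - {min: 41, max: 50, score: 1}
    - {min: 51, max: 90, score: 0}
    - {min: 91, max: 110, score: 1}
    - {min: 111, max: 130, score: 2}
    - {min: 131, score: 3}
avpu:
  Alert: 0
  Verbal: 3
  Pain: 3
  Unresponsive: 3
oxygen_score: 2
band_cutpoints: [4, 6]
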