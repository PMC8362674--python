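# Cover-abundance scales: ordered code -> percent class midpoint.
# Codes not listed are parsed as plain percentages.
scales:
  - name: braun_blanquet
    midpoints:
      r: 0.1
      "+": 0.5
      "1": 2.5
      "2": 15.0
      "3": 37.5
      "4": 62.5
      "5": 87.5
  # Old (7-degree) scale with 2m/2a/2b split
  - name: braun_blanquet_extended
    midpoints:
      r: 0.1
      "+": 0.5
      "1": 2.5
      "2m": 4.0
      "2a": 10.0
      "2b": 20.0
      "3": 37.5
      "4": 62.5
      "5": 87.5
  - name: percent
    midpoints: {}
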