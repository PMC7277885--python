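# Default Index of Caring Complexity matrix:
# NEWS band (rows) x mICD dependence level (columns) -> ICC class.
stable:
  low: Low
  average: Medium
  high: High
unstable:
  low: Medium
  average: Medium
  high: High
critical:
  low: High
  average: High
  high: High
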