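{
  "comment": "Index classification scheme: each entry is [lower bound, label]; intervals are half-open [lo, next_lo), values on a bound take the upper category.",
  "scheme": [
    [0, "excellent"],
    [50, "good"],
    [100, "lightly polluted"],
    [150, "moderately polluted"],
    [200, "heavily polluted"],
    [300, "severely polluted"]
  ]
}
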