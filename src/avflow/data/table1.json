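{
  "P1-IN": {
    "rao": {"R1": 6.88, "R2": 59.80, "C": 0.010},
    "uao": {"R1": 6.88, "R2": 59.80, "C": 0.010},
    "vo": {"R1": 7.00, "R2": 10.30, "C": 10.50}
  },
  "P2-IN": {
    "rao": {"R1": 3.20, "R2": 53.20, "C": 0.009},
    "uao": {"R1": 3.20, "R2": 53.20, "C": 0.009},
    "vo": {"R1": 7.00, "R2": 7.50, "C": 5.25}
  }
}
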