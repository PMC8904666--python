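{
  "MBI-EE": {"raw": 27, "t": 50.70},
  "MBI-DP": {"raw": 10, "t": 53.76},
  "MZSIB": {"raw": 3, "t": null},
  "PFI-BC": {"raw": 14, "t": null}
}
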