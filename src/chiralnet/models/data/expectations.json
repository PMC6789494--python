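{
  "theta0": {"order": 0, "verdict": null},
  "frank": {"order": 1, "verdict": "accept"},
  "calvin": {"order": 2, "verdict": "reject"},
  "aped": {"order": 4, "verdict": "accept"},
  "replicator": {"order": 2, "verdict": "accept"},
  "iwamoto_perfect": {"order": 2, "verdict": "accept"},
  "iwamoto_imperfect": {"order": 2, "verdict": "accept"}
}
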