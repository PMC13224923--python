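{
  "version": "KDIGO 2012 CKD eGFR-albuminuria prognosis grid",
  "risk": {
    "G1": {"A1": "low", "A2": "moderate", "A3": "high"},
    "G2": {"A1": "low", "A2": "moderate", "A3": "high"},
    "G3a": {"A1": "moderate", "A2": "high", "A3": "very_high"},
    "G3b": {"A1": "high", "A2": "very_high", "A3": "very_high"},
    "G4": {"A1": "very_high", "A2": "very_high", "A3": "very_high"},
    "G5": {"A1": "very_high", "A2": "very_high", "A3": "very_high"}
  }
}
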