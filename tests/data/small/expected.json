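{
 "expected_disorder_modality": {
  "orgA": "low",
  "orgB": "medium",
  "orgC": "medium",
  "orgD": "medium",
  "orgE": "high"
 },
 "expected_disorder_pct41": {
  "orgA": 0.0,
  "orgB": 20.0,
  "orgC": 20.0,
  "orgD": 20.0,
  "orgE": 60.25
 },
 "expected_gc_modality": {
  "orgA": "low",
  "orgB": "medium",
  "orgC": "medium",
  "orgD": "medium",
  "orgE": "high"
 },
 "guaranteed_rule": {
  "body": [
   "gc=high"
  ],
  "confidence": 1.0,
  "head": [
   "disorder=high"
  ],
  "lift": 5.0,
  "support": 0.2
 }
}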