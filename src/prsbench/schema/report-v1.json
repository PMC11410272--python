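{
  "schema": "prsbench standardised report",
  "version": "1.0",
  "required": {
    "schema_version": "string",
    "provenance": "object",
    "distribution": "any",
    "traits": "object",
    "carrier_equivalence": "object",
    "multivariate": "object"
  },
  "provenance_required": {
    "package_version": "string",
    "config_hash": "string",
    "seed": "integer",
    "incidence_mode": "string",
    "timestamp": "string"
  },
  "notes": [
    "Every suppressed estimate carries a gate_reason.",
    "Comparison blocks record n_bootstrap and seed.",
    "Determinism contract: identical inputs + config + seed give identical content apart from provenance.timestamp."
  ]
}
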