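{
  "schema_version": 1,
  "name": "Saccharomyces cerevisiae",
  "condition": "YEPD",
  "doubling_time_h": 1.5,
  "mrna_lifetime_h": 0.36666666666666664,
  "total_mrna_per_cell": 29000,
  "total_messages_per_cycle": 120000,
  "total_protein": 50000000
}
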