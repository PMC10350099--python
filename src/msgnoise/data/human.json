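{
  "schema_version": 1,
  "name": "Homo sapiens",
  "condition": "tissue",
  "doubling_time_h": 24,
  "mrna_lifetime_h": 14,
  "total_mrna_per_cell": 360000,
  "total_messages_per_cycle": 620000,
  "total_protein": 2000000000
}
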