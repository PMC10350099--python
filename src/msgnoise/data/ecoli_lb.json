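{
  "schema_version": 1,
  "name": "Escherichia coli",
  "condition": "LB",
  "doubling_time_h": 0.5,
  "mrna_lifetime_h": 0.041666666666666664,
  "total_mrna_per_cell": 7800,
  "total_messages_per_cycle": 94000,
  "total_protein": 3000000
}
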