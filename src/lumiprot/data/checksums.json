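{
  "version": 1,
  "sha256": {
    "ctd_groups.tsv": "706e5d772580df84fa75c21c2ec03f69d540fc0f02243daae702e67857ca2f99",
    "pseaac_properties.tsv": "3c7af7829cfcec63b71f7c804ea47268eac481f787f86f5216c04083281feca4"
  }
}
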