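{
  "schema": "oncoreg-query/1",
  "root_class": "Patient",
  "constraints": [],
  "name": "All patients"
}
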