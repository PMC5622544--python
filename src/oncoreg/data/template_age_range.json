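{
  "schema": "oncoreg-query/1",
  "root_class": "Patient",
  "constraints": [
    {"kind": "filter", "property": "age", "op": ">=", "value": {"param": "age_min"}},
    {"kind": "filter", "property": "age", "op": "<=", "value": {"param": "age_max"}}
  ],
  "name": "Patients in an age range"
}
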