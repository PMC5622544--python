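{
  "schema": "oncoreg-query/1",
  "root_class": "Patient",
  "constraints": [
    {"kind": "filter", "property": "age", "op": ">", "value": 70},
    {"kind": "link", "property": "hasDiagnosis", "class": "Diagnosis",
     "constraints": [
       {"kind": "link", "property": "hasPathologicalStructure",
        "class": "Pathological_structure", "constraints": []}
     ]}
  ],
  "aggregation": {"function": "count", "distinct": true, "group_node": [1, 0],
                  "group_prop": null, "target_prop": null},
  "name": "Patients over 70 by cancer type"
}
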