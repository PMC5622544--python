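{
  "schema": "oncoreg-query/1",
  "root_class": "Patient",
  "constraints": [
    {"kind": "link", "property": "hasDiagnosis", "class": "Diagnosis",
     "constraints": [
       {"kind": "link", "property": "hasPathologicalStructure",
        "class": "Colorectal_cancer", "constraints": []}
     ]}
  ],
  "name": "Patients with colorectal cancer"
}
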