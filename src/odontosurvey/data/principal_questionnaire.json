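{
  "description": "Structure of the self-administered school-principal questionnaire (sociodemographic characterization of the school unit): 84 questions. No per-class breakdown is published, so the definition carries a single class.",
  "name": "principal_school_questionnaire",
  "classes": [
    {"label": "School characterization", "first": 1, "last": 84}
  ]
}
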