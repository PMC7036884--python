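{
  "description": "Structure of the self-administered student questionnaire (adapted from the Brazilian National School Health Survey, PeNSE 2015): 146 questions in 12 thematic classes with inclusive question-number ranges.",
  "name": "student_epidemiological_questionnaire",
  "classes": [
    {"label": "Personal characteristics", "first": 1, "last": 18},
    {"label": "Nutritional data", "first": 19, "last": 62},
    {"label": "Physical activities", "first": 63, "last": 72},
    {"label": "Smoking", "first": 73, "last": 81},
    {"label": "Alcohol consumption", "first": 82, "last": 89},
    {"label": "Drug use", "first": 90, "last": 95},
    {"label": "Personal relationships", "first": 96, "last": 107},
    {"label": "Hygiene and oral health", "first": 108, "last": 113},
    {"label": "Security", "first": 114, "last": 130},
    {"label": "Access to health services", "first": 131, "last": 138},
    {"label": "Body image", "first": 139, "last": 145},
    {"label": "Your opinion", "first": 146, "last": 146}
  ]
}
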