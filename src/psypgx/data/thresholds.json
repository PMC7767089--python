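{
  "_comment": "Minimum therapeutic daily dose (mg/d) per antipsychotic, from the drug datasheets and Stahl's Prescriber's Guide. A prescription strictly below its threshold is flagged infratherapeutic.",
  "thresholds": {
    "amisulpride": 400,
    "aripiprazole": 10,
    "asenapine": 5,
    "olanzapine": 10,
    "paliperidone": 6,
    "quetiapine": 400,
    "risperidone": 2,
    "clozapine": 300,
    "levomepromazine": 100,
    "chlorpromazine": 200
  }
}
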