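{
  "provenance": "Oral chlorpromazine-equivalence factors (mg chlorpromazine per mg drug) from published consensus means: Gardner DM et al., Am J Psychiatry 2010;167:686-693 and Leucht S et al., Schizophr Bull 2014;40:314-326. Long-acting injectables are expressed as mg/day (monthly dose / interval days) before the factor is applied; IM factors equal the oral factor by default. Editable configuration, not ground truth.",
  "factors": {
    "chlorpromazine": {"oral": 1.0},
    "olanzapine": {"oral": 20.0, "IM": 20.0},
    "risperidone": {"oral": 50.0, "IM": 50.0},
    "quetiapine": {"oral": 1.33},
    "aripiprazole": {"oral": 13.33, "IM": 13.33},
    "clozapine": {"oral": 2.0},
    "amisulpride": {"oral": 1.0},
    "asenapine": {"oral": 10.0},
    "paliperidone": {"oral": 66.67, "IM": 66.67},
    "levomepromazine": {"oral": 1.0}
  }
}
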