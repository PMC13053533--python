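# SYNTHETIC illustrative seven-predictor mortality score.
# These numbers are NOT the published clinical coefficients (which must be
# obtained from the original development publication / calculator) and must
# never be used for patient care. They exist so the config schema and the
# examples can run end to end.
label: synthetic-demo-score (non-clinical)
intercept: -1.9
coefficients:
  mean_arterial_pressure: -0.04
  age: 0.032
  bun: 0.04
  intubation: 1.9
  sodium: -0.024
  body_temperature: 0.24
  albumin: -1.75
predictors:
  - {name: mean_arterial_pressure, kind: continuous, unit: mm Hg}
  - {name: age, kind: continuous, unit: years}
  - {name: bun, kind: continuous, unit: mg/dL}
  - {name: intubation, kind: binary, unit: ""}
  - {name: sodium, kind: continuous, unit: mmol/L}
  - {name: body_temperature, kind: continuous, unit: degC}
  - {name: albumin, kind: continuous, unit: g/dL}
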