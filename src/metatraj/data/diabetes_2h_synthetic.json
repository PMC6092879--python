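{
 "name": "diabetes_2h_synthetic",
 "description": "SYNTHETIC stand-in diabetes risk score (logistic), 2-h post-load glucose variant. The coefficients are illustrative values constructed for this package, not a transcription of any published equation; replace with a validated score definition for substantive use.",
 "link": "logistic",
 "horizon_years": 8,
 "intercept": -1.6,
 "terms": [
  {"input": "age", "transform": "identity", "center": 55.0, "coef": 0.05},
  {"input": "bmi", "transform": "identity", "center": 26.0, "coef": 0.08},
  {"input": "glu2h", "transform": "identity", "center": 5.5, "coef": 0.45},
  {"input": "fh_diabetes", "transform": "identity", "coef": 0.8},
  {"input": "smoking", "transform": "identity", "coef": 0.15},
  {"input": "sex", "transform": "identity", "coef": 0.2}
 ]
}
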