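{
 "name": "framingham_cvd_2008",
 "description": "10-year general cardiovascular disease risk (D'Agostino et al. 2008, sex-specific Cox equation, lipids converted from mmol/L to mg/dL; blood-pressure treatment is not modelled so the untreated SBP coefficients are used; diabetes is defined as FPG >= 7.0 mmol/L).",
 "link": "cox",
 "horizon_years": 10,
 "terms": [
  {"input": "age", "transform": "log", "coef": {"male": 3.06117, "female": 2.32888}},
  {"input": "tc", "transform": "log", "scale": 38.67, "coef": {"male": 1.1237, "female": 1.20904}},
  {"input": "hdl", "transform": "log", "scale": 38.67, "coef": {"male": -0.93263, "female": -0.70833}},
  {"input": "sbp", "transform": "log", "coef": {"male": 1.93303, "female": 2.76157}},
  {"input": "smoking", "transform": "identity", "coef": {"male": 0.65451, "female": 0.52873}},
  {"input": "fpg", "transform": "threshold", "threshold": 7.0, "coef": {"male": 0.57367, "female": 0.69154}}
 ],
 "baseline_survival": {"male": 0.88936, "female": 0.95012},
 "lp_mean": {"male": 23.9802, "female": 26.1931}
}
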