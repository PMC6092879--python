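{
 "alpha_b": [
  25.0,
  1.0,
  -0.15
 ],
 "Gamma_b": [
  [
   -0.3,
   0.3,
   -0.6,
   0.4,
   0.2,
   0.02
  ],
  [
   0.05,
   0.0,
   -0.1,
   0.0,
   0.0,
   -0.01
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 ],
 "Psi_b": [
  [
   11.999999999999998,
   0.4898979485566357,
   -0.07745966692414834
  ],
  [
   0.4898979485566357,
   0.5000000000000001,
   -0.0316227766016838
  ],
  [
   -0.07745966692414834,
   -0.0316227766016838,
   0.049999999999999996
  ]
 ],
 "B": [
  [
   0.262,
   0.0
  ],
  [
   0.0821,
   0.1984
  ],
  [
   0.0,
   0.0
  ],
  [
   0.108,
   0.0
  ],
  [
   -0.0396,
   0.2325
  ],
  [
   0.4459,
   0.0
  ],
  [
   -0.4808,
   0.9802
  ],
  [
   -0.3514,
   0.0
  ],
  [
   -0.04,
   0.0
  ]
 ],
 "alpha_f": [
  -1.2500000000000009,
  -2.1009,
  0.03,
  117.3,
  3.7575000000000003,
  -5.347500000000001,
  11.1398,
  10.185,
  1.02
 ],
 "Gamma_f": [
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.0,
   0.05,
   0.0,
   0.05,
   0.0,
   0.002
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   1.5,
   0.5,
   0.0,
   0.0,
   1.0,
   0.4
  ],
  [
   0.5,
   0.0,
   0.0,
   0.0,
   0.3,
   0.05
  ],
  [
   0.1,
   0.0,
   0.1,
   0.0,
   0.15,
   0.02
  ],
  [
   0.0,
   0.0,
   0.05,
   0.0,
   0.0,
   0.0
  ],
  [
   -0.25,
   -0.02,
   -0.05,
   0.0,
   0.0,
   0.002
  ],
  [
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ]
 ],
 "Psi_zeta": [
  [
   0.25,
   -0.020000000000000004,
   0.0,
   1.0954451150103324,
   0.0,
   0.06708203932499368,
   0.0,
   -0.0316227766016838,
   0.0
  ],
  [
   -0.020000000000000004,
   0.04000000000000001,
   -0.006000000000000001,
   0.0,
   0.3,
   0.0,
   0.015491933384829671,
   0.0,
   -0.006000000000000001
  ],
  [
   0.0,
   -0.006000000000000001,
   0.010000000000000002,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   1.0954451150103324,
   0.0,
   0.0,
   120.0,
   -10.954451150103324,
   1.4696938456699067,
   0.0,
   -0.3464101615137755,
   0.0
  ],
  [
   0.0,
   0.3,
   0.0,
   -10.954451150103324,
   25.0,
   0.0,
   0.0,
   0.0,
   0.0
  ],
  [
   0.06708203932499368,
   0.0,
   0.0,
   1.4696938456699067,
   0.0,
   0.7999999999999999,
   -0.06928203230275509,
   -0.0565685424949238,
   0.0
  ],
  [
   0.0,
   0.015491933384829671,
   0.0,
   0.0,
   0.0,
   -0.06928203230275509,
   0.15000000000000002,
   0.0,
   0.0
  ],
  [
   -0.0316227766016838,
   0.0,
   0.0,
   -0.3464101615137755,
   0.0,
   -0.0565685424949238,
   0.0,
   0.1,
   -0.00632455532033676
  ],
  [
   0.0,
   -0.006000000000000001,
   0.0,
   0.0,
   0.0,
   0.0,
   0.0,
   -0.00632455532033676,
   0.010000000000000002
  ]
 ],
 "omega": 0.05,
 "lam": [
  1.0,
  1.8,
  0.5
 ],
 "nu": [
  0.0,
  -4.04,
  2.75
 ],
 "kappa": [
  [
   0.0031,
   0.2129,
   0.01,
   0.1168
  ],
  [
   0.0716,
   -0.1411,
   0.3047,
   0.3496
  ],
  [
   0.0101,
   -0.0457,
   0.1854,
   0.0563
  ]
 ],
 "theta": [
  0.3,
  0.15,
  2.5,
  0.1,
  40.0,
  0.15,
  0.02
 ]
}
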