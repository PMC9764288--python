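# Three-basin model: pro-S-reactive, pro-R-reactive, nonproductive.
# Stationary occupancies 0.30 / 0.075 / 0.625 -> epimeric excess 60%.
# Rates are in 1/ps (rows sum to zero); emissions are truncated normals
# (mean, sd) for the O-H distance d (Angstrom) and the theta1/theta2 angles
# (degrees) of each hydrogen.
states:
  - label: proS_NAC
    emissions:
      pro_S: {d: [2.3, 0.1], theta1: [120.0, 5.0], theta2: [160.0, 6.0]}
      pro_R: {d: [5.0, 0.8], theta1: [115.0, 15.0], theta2: [110.0, 15.0]}
  - label: proR_NAC
    emissions:
      pro_S: {d: [5.0, 0.8], theta1: [115.0, 15.0], theta2: [110.0, 15.0]}
      pro_R: {d: [2.3, 0.1], theta1: [120.0, 5.0], theta2: [160.0, 6.0]}
  - label: nonproductive_1
    emissions:
      pro_S: {d: [5.0, 0.8], theta1: [115.0, 15.0], theta2: [110.0, 15.0]}
      pro_R: {d: [5.0, 0.8], theta1: [115.0, 15.0], theta2: [110.0, 15.0]}
rates:
  - [-0.35,    0.0375,  0.3125]
  - [0.15,    -0.4625,  0.3125]
  - [0.15,     0.0375, -0.1875]
initial_distribution: [0.3, 0.075, 0.625]
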