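# Scoring config for trajectories written by `nac simulate`.
# Matchers may restrict chain/resseq; names suffice for the synthetic frames.
selection:
  fe: {name: FE}
  oxo: {name: O1}
  c_target: {name: C6}
  h_pro_r: {name: H6R}
  h_pro_s: {name: H6S}
  pyrrole: [{name: NA}, {name: NB}, {name: NC}, {name: ND}]
  allow_virtual_oxo: true
criteria:
  d_max: 2.7
  theta1_min: 100.0
  theta1_max: 140.0
  theta2_min: 140.0
stride: 1
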