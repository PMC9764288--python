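# Equal-budget comparison pair: 5 x 1000 ps vs 50 x 100 ps production,
# both evaluated at 1 ps so the arms differ only in replica structure.
- name: long_5_replicas
  n_replicas: 5
  warmup_ps: 30.0
  equilibration_ps: 20.0
  production_ps: 1000.0
  snapshot_interval_ps: 50.0
  nac_eval_interval_ps: 1.0
- name: short_50_replicas
  n_replicas: 50
  warmup_ps: 30.0
  equilibration_ps: 20.0
  production_ps: 100.0
  snapshot_interval_ps: 5.0
  nac_eval_interval_ps: 1.0
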