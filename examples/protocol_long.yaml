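# Few-long preset: 5 replicas, 2 ns equilibration, 20 ns production,
# snapshots every 50 ps, NAC evaluation every 1 ps.
name: long_5x20ns
n_replicas: 5
warmup_ps: 30.0
equilibration_ps: 2000.0
production_ps: 20000.0
snapshot_interval_ps: 50.0
nac_eval_interval_ps: 1.0
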