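# Many-short preset: 50 independently initialized replicas of 100 ps each
# (30 ps warm-up + 20 ps equilibration + 50 ps production), snapshots every
# 5 ps, NAC evaluation every 20 fs.
name: short_50x100ps
n_replicas: 50
warmup_ps: 30.0
equilibration_ps: 20.0
production_ps: 50.0
snapshot_interval_ps: 5.0
nac_eval_interval_ps: 0.02
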