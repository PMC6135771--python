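# Coarse-grained REX run of the GB1m3-like preset.  CA snapshots at the
# lowest temperature are written as a multi-model PDB (state_interval > 0).
model:
  kind: cg
  preset: GB1m3-like
ladder:
  t_min: 270.0
  t_max: 550.0
  n_replicas: 5
run:
  n_sweeps: 3500
  exchange_interval: 2
  production_fraction: 0.6
  seed: 1
  state_interval: 20
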