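# Replica-exchange run of the GB1p-like zipper preset over the 270-400 K
# ladder.  Run with:
#   hairpinmc simulate examples/zipper_gb1p.yaml --out-dir out/
#   hairpinmc analyze out/
#   hairpinmc report out/
model:
  kind: zipper
  preset: GB1p-like
ladder:
  t_min: 270.0
  t_max: 400.0
  n_replicas: 8
run:
  n_sweeps: 20000
  exchange_interval: 2
  production_fraction: 0.6
  seed: 1
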