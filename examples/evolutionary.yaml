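# Replicator-only evolutionary run: k_a declines to its minimum viable value.
experiment: evolutionary
L: 64
seed: 11
init:
  density_replicators: 0.3
  ka_init: 1.0
run:
  t_end: 200000
  sample_every: 500
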