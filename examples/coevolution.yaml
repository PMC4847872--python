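# Co-evolution of k_a and beta under a long replication duration.
experiment: coevolution
L: 128
k_diss: 0.1
dt_repl: 4.0
evolve_beta: true
seed: 1
init:
  density_replicators: 0.2
  density_parasites: 0.2
  ka_init: 1.0
  beta_init: 1.0
run:
  t_end: 5000
  sample_every: 100
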