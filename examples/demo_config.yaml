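# Demo synthetic study: two populations responding to the default ensemble
# (88 sequences: 6 base classes, 11 variants, 8 directions).
seed: 0

ensemble: {}  # default composition

population:
  neurons_per_class:
    grating: 10
    flow-1dot: 10
    flow-3dot: 10
    flow-random: 10
    flow-radial: 10
    flow-rotation: 10
  noise_scale: 0.05
  n_time: 16

# system B: same stated world, higher noise (a degraded twin)
population_b:
  neurons_per_class:
    grating: 10
    flow-1dot: 10
    flow-3dot: 10
    flow-random: 10
    flow-radial: 10
    flow-rotation: 10
  noise_scale: 0.15
  n_time: 16

decoding:
  n_dims: 3
  grouping: class-direction

encoding:
  rank: 4
  k_neighbors: 7
  n_dims: 3

tubularity:
  n_boot: 300
  n_comparisons: 2

alignment:
  lp_folds: 5
  dsa_rank: 3
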