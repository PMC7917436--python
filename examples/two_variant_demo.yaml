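# Two-variant in-silico comparison: a "loose" single-mutant-like pocket vs a
# "crowded" multi-mutant-like pocket.  All analysis parameters are shared.
output_dir: demo_out
seed: 7
pca_variance_target: 0.99
min_cluster_size: 10
variants:
  c426a_like:
    n_frames: 2000
    classes:
      - {name: C_IN, population: 0.78, states: {Q489: in, N468: in},
         exc_mean_ev: 3.22, emi_mean_ev: 2.82}
      - {name: C_OUT_solv, population: 0.17, states: {Q489: out, N468: in},
         distance_mean: {Q489: 8.0}, exc_mean_ev: 3.23, emi_mean_ev: 2.84}
      - {name: C_OUT_buried, population: 0.05, states: {Q489: out, N468: in},
         distance_mean: {Q489: 5.6}, exc_mean_ev: 3.27, emi_mean_ev: 2.88}
    ring: {separation: 5.0, ring_jitter: 0.6}
  ilov_like:
    n_frames: 2000
    classes:
      - {name: C1_IN, population: 0.15, states: {Q489: in, N468: in},
         exc_mean_ev: 3.24, emi_mean_ev: 2.85}
      - {name: C2_OUT, population: 0.85, states: {Q489: out, N468: in},
         distance_mean: {Q489: 8.0}, exc_mean_ev: 3.26, emi_mean_ev: 2.875}
    ring: {separation: 3.5, ring_jitter: 0.3}
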