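# Example loopshift run configuration.
# `preset: quick` is 3 replicas x 500 frames; `paper_scale` is 15 x 5,000.
seed: 1
preset: quick

simulate:
  variants:
    wt_like:
      stationary: [0.95, 0.04, 0.01]   # closed-dominant chain
      interaction_sites: [[28, NZ, N], [40, OE1, O]]
      residue_names: {28: LYS, 40: GLU}
      plant_interactions:
        - {donor: [28, NZ], acceptor: [40, OE1], state: wide_open, occupancy: 0.1}
    chimera_like:
      stationary: [0.45, 0.25, 0.30]   # wide-open stabilized
      sigma_overrides: {10: 0.6}       # planted 2x flexibility on residue 10
      interaction_sites: [[28, NZ, N], [40, OE1, O]]
      residue_names: {28: LYS, 40: GLU}
      plant_interactions:
        - {donor: [28, NZ], acceptor: [40, OE1], state: wide_open, occupancy: 0.9}

states:
  cutoffs: {closed: 1.5, open: 1.5, wide_open: 1.5}
  bin_width: 0.16
  fraction_cutoffs: [1.5, 2.0]

rmsf_diff:
  pair: [chimera_like, wt_like]
  fdr: 0.05
  test: welch

network_diff:
  pair: [chimera_like, wt_like]
  state: wide_open
  mode: heavy_only

evb:
  h12: 3.0
  dE: 0.0
  samples_per_window: 1000
  n_bins: 100

lra:
  epsilon_in: 4.0
  n_frames: 10000
  effects: {5: 2.0, 9: -1.2}
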