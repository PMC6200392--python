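# Demo pipeline configuration: 20 fast-condition events, full analysis.
seed: 1
n_events: 20
keep_kymographs: false

condition:
  name: demo_low_crosslinker
  overlap_range: [800, 5000]      # initial overlap L0 (nm)
  sliding_efficiency: 0.095       # S, per-complex duty-ratio analogue
  occupancy: 0.05                 # a, sliding-competent site occupancy
  endtag_fraction: 0.3            # end-tag length per unit filament length
  rho_untagged_mean: 3.5          # A.U./nm, event-to-event mean
  rho_untagged_sd: 1.7
  duration: 300.0                 # s

analysis:
  stall_threshold: 2.0            # nm/s sustained drift counts as stalled
  stall_window_s: 10.0
  smoothing_window: 5             # frames, velocity smoothing
  occupancy_min: 0.01
  occupancy_max: 0.10
  occupancy_steps: 10
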