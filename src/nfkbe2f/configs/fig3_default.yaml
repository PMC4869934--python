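# TNFα effect on cell-cycle timing: 200 cells per arm followed through two
# divisions; treatment 30 h into a 60 h recording.
population:
  n_cells: 200
  treatment_time_h: 30.0
  record_h: 60.0
  dose_scale: 1.0
  simulate: false
n_boot: 2000
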