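# Dual-reporter stable line regime: untreated cells, mean cycle ~20 h.
population:
  n_cells: 200
  treatment_time_h: 30.0
  record_h: 60.0
  dose_scale: 0.0
  simulate: false
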