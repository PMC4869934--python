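# Dual-reporter line: E2F-1-peak alignment and phase-dependent response.
population:
  n_cells: 128
  treatment_time_h: 30.0
  record_h: 50.0
  dose_scale: 1.0
method: e2f1
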