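# Phase-dependent first NF-κB response, mitosis-timing virtual sync.
population:
  n_cells: 240
  treatment_time_h: 30.0
  record_h: 50.0
  dose_scale: 1.0
method: mitosis
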