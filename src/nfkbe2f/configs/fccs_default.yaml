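# FCCS Kd recovery: 46 triplets at 10% channel noise, truth 12 nM.
true_kd_nM: 12.0
n: 46
abundance_range_nM: [5.0, 200.0]
noise_sd: 0.10
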