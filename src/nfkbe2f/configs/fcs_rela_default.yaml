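# FCS molecule counting, RelA-DsRedxp: printed confocal/compartment volumes.
target_total_molecules: 310000
nuclear_fraction: 0.08
v_conf_fL: 0.59
v_nuc_fL: 1420.0
v_cyt_fL: 6110.0
n_replicates: 20
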