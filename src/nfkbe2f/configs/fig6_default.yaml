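# Refractory period: revised-model cells starting from the nuclear
# RelA·E2F-1 co-expression state vs base-variant cells, sustained TNFα.
n_cells_per_arm: 20
heterogeneity_cv: 0.03
e2f1_pool_nM: 150.0
t_end_min: 1500.0
dt_min: 2.0
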