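# Desk-scale experimental grid: admixture time x ancestry proportion x
# switch-error rate, 3 replicates of 30 individuals per cell.
t_values: [5, 10, 15]
p_values: [0.2, 0.5, 0.8]
switch_rates: [0.0, 0.03]
n_replicates: 3
n_individuals: 30
model: markov
n_chrom: 22
chrom_length_cm: 163.2
marker_spacing_cm: 0.5
n_hap_per_pop: 70
fst: 0.15
correction: false
master_seed: 1
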