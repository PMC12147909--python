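# Small demonstration cohort: 6 patients, 3 blood timepoints plus a
# baseline tumor each. Analysis parameters are the published defaults
# (50-read filter, 0.2% expansion threshold, alpha 0.05).
out_dir: clonotrace_out
seed: 0
n_patients: 6
n_timepoints: 3
n_background_clones: 800
n_hyperexpanded: 4
total_reads: 200000
nonexpanded_depletion: 0.6
min_reads: 50
expansion_threshold: 0.002
alpha: 0.05
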