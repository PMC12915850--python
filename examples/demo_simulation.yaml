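# three-cohort case-control demo: moderate planted signal + batch bias
n_studies: 3
cases_per_study: 30
controls_per_study: 30
n_taxa: 120
n_disease_taxa: 8
n_protective_taxa: 4
effect_size: 1.5
batch_sd: 0.5
seed: 11
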