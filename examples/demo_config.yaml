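# analysis thresholds (published defaults) and reduced CV budget for the demo
min_read_count: 10000000
max_unclassified: 0.30
max_bmi: 30.0
min_study_n: 10
abundance_cutoff: 1.0e-4
occurrence_cutoff: 0.01
fdr_threshold: 0.1
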