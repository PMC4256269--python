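# Synthetic-data generation: field-scale study design.
[model]
immigrant_fraction = 0.1

[panel]
# 12 linked markers over 41 cM (suppressor at 11.5 cM), 9 unlinked
# controls, 2-8 alleles per marker, novel immigrant alleles at 4 markers
n_linked = 12
n_unlinked = 9
n_novel = 4
span_cm = 41.0

[samples]
# 48 diploids sampled before the immigrant arrives and 50 generations
# (about five years) later
n = 48
sample_times = [0, 50]
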