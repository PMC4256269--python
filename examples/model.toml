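# Sweep-model parameters: the Samoan default scenario.
[model]
# fraction of females infected with the male-killer at generation 0
prevalence0 = 0.99
# viability of infected male zygotes by suppressor genotype
survival_ss_male_infected = 0.0   # unsuppressed males all die
survival_Ss_male_infected = 0.5   # partially dominant rescue (~40% observed)
survival_SS_male_infected = 1.0
# cytoplasmic incompatibility: fraction of offspring dying when an
# uninfected female mates an infected male
ci_level = 1.0
# recombination fraction(s) between the suppressor and the neutral locus
# (male meiosis only; give two values for the three-locus model)
rec_fractions = [0.05]
# the infected SS immigrant male's share of generation-0 matings
immigrant_fraction = 0.1
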