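# Methods

## The sweep model

The core object is a deterministic recursion over the frequencies of
diplotypes (unordered pairs of gametic haplotypes) crossed with *Wolbachia*
infection status, tracked separately in females and males. Haplotypes span
the suppressor locus (*S*/*s*) plus one or two linked neutral biallelic
loci; allele "1" at any locus is the variant carried by the immigrant
suppressor chromosome. A generation consists of:

1. **Gamete pools.** Each adult female contributes her two haplotypes at ½
   each (no recombination in female Lepidoptera); male gametes recombine
   with probability `rec_fractions[i]` in each adjacent interval,
   independently across intervals (no interference). Gametes are labelled
   by the parent's infection status. Every adult male receives an equal
   share of matings.
2. **Zygotes.** Random union of gamete pools. Offspring infection status
   equals the mother's (strict maternal transmission). Offspring of
   uninfected mothers sired by infected fathers die at rate `ci_level`
   (cytoplasmic incompatibility; complete by default).
3. **Male-killing.** Infected male zygotes survive at
   `(survival_ss, survival_Ss, survival_SS) = (0, 0.5, 1)` by default —
   the partially dominant rescue implied by the empirical ~40% survival of
   suppressor-bearing sons in mapping crosses. Females and uninfected
   males are untouched. Each sex is renormalized to frequencies; a 1:1
   primary sex ratio is assumed throughout, and sex-ratio selection is
   implicit: males are rare, so surviving males are hugely overrepresented
   in transmission.

The model is infinite-population (no drift) and cost-free for the
suppressor; stochastic and spatial extensions are deliberately out of
scope, as is fitting the model to field samples.

**Initial conditions.** The resident population is fixed for the resident
haplotype, with `prevalence0 = 0.99` of females infected. The "single
infected immigrant male" of a finite population cannot be represented
literally in a deterministic model; it is operationalized as the immigrant
male's share `immigrant_fraction` of the generation-0 male gamete pool.
The default is **0.1**, calibrated so that the model reproduces the
regime the model is meant to describe: with nearly all matings involving
rare males, the immigrant sires an appreciable fraction of the first
brood, almost every surviving first-generation male is *Ss* (male *S*
frequency 0.423, approaching but not exceeding ½) and the suppressor
chromosome jumps to 0.236 population-wide (approaching but not exceeding
¼). Under this default the equilibrium hitchhiking profile takes a fully
associated neutral allele to 35% at free recombination (r = 0.5) and to
89% at 5 cM. The sweep itself is insensitive to this choice: the
suppressor exceeds 95% by generation 15 for any immigrant fraction from
0.005 to 0.05 as well (a sensitivity sweep is part of the test suite).

**Summaries.** Allele frequencies and LD are computed on the adult
haplotype pool with the sexes weighted equally, since each sex contributes
half of the genes to the next generation. `D` is the classical gametic
covariance and `r_corr` its correlation normalization; monomorphic loci
return 0 with a flag. Equilibria are declared when the largest
per-generation change in any state frequency falls below `tol = 1e-10`
(default cap 5000 generations; non-convergence is flagged, never silently
truncated).

## Drift null models

Two independent routes to the probability that an allele at frequency
`p0` is absent after `t` generations in a population of effective size
`N`:

* an **exact Markov chain**: binomial resampling of `2N` gene copies,
  started at `round(2N·p0)` copies (the rounding matters and is
  documented: 0.22 × 360 = 79.2), absorbed at zero;
* **Kimura's diffusion series**. The eigenfunction expansion of the drift
  diffusion, integrated as probability flux into the loss boundary, gives

  `P_loss(t) = q − Σ_{i≥1} p·q·(2i+1)·F(1−i, i+2; 2; p)·e^{−i(i+1)t/4N}`

  with `q = 1−p` and `F` the Gauss hypergeometric polynomial. The series
  is truncated when terms fall below 1e-12 (10,000-term cap). It tends to
  0 as `t→0` and to `q` as `t→∞`.

Published reprints of this solution differ in sign and normalization
conventions; the form above was selected by requiring agreement with the
exact chain. The agreement is 0.003 absolute at N = 180 and ~1e-5 at
N = 500, but the diffusion error grows as N shrinks: ~0.006 at N = 122
and ~0.010 at N = 100 (for p0 = 0.22, t = 40; confirmed against 4×10⁵
direct Wright–Fisher simulations). Claims of 0.005-level agreement should
therefore be restricted to N ≳ 150 for parameters in this range.
Generations are the native time unit; `years_to_generations` applies the
default 10 generations per year (36-day egg-to-adult period).

## Sweep-detection statistics

The pipeline consumes *phased* haplotype samples (the field workflow
phases SNP genotypes beforehand; a naive counting-based phaser is included
for unambiguous individuals only, and never guesses at ambiguous ones).
Individuals missing at a locus are dropped locus-wise.

* **Heterogeneity.** G = 2·Σ O·ln(O/E) on the samples × alleles table.
  p-values: asymptotic χ² and Monte-Carlo with both margins fixed
  (Patefield sampling), add-one estimator `(1+#{G*≥G})/(B+1)` — exactly
  valid at any B. The documented default is B = 100,000 for single
  tests; multi-locus studies in the test suite use B = 1000, which leaves
  the Holm decisions exact (the MC p-value is valid at any B) while
  keeping hundred-replicate studies fast.
* **Swept-allele identification.** Where samples are heterogeneous,
  adjusted standardized residuals (cell residual over its estimated
  standard error under independence) are computed; among alleles whose
  frequency increased, the largest residual is declared swept, its column
  removed, and the reduced table retested until homogeneous. With only
  two alleles the procedure is undefined (each allele contributes equally)
  and is refused.
* **F_ST.** Variance-components estimator on haploid allele counts
  (Weir–Cockerham-style ANOVA over alleles), with Nei's G_ST reported
  alongside and a permutation p-value from shuffling allele copies between
  samples. The estimator is unbiased, hence slightly negative (≈ −1/(n−1))
  for coinciding samples.
* **Diversity.** A_E = 1/Σp²; sequence statistics (S, π, Watterson θ, Hd
  with the n/(n−1) correction, mean pairwise differences k, Tajima's D)
  computed on aligned allele sequences with gap-containing columns
  excluded (indel variation is not used).
* **LD.** Likelihood-ratio independence test on the two-locus haplotype
  table, null distribution by permuting one locus's alleles across
  haplotypes. Only significance is reported — the magnitude of LD is not
  standardized across allele-frequency distributions.
* **Multiple testing.** Holm step-down (the standard reading of
  "sequential Bonferroni"), via statsmodels.

## Synthetic data

The generator produces the inputs the analysis assumes, not a full
coalescent model of the species:

* **Panels.** 12 linked markers spanning 41 cM at anchor positions
  matching the mapped chromosome (C at +8, the D/E/F cluster at +11…+12,
  G at +17), suppressor at 11.5 cM; 9 unlinked markers on 8 other linkage
  groups. Pre-sweep allele frequencies are broken-stick (sorted uniform
  stick-breaking) with 2–8 alleles per marker — the field profiles are
  only available graphically, so this is a realism choice, configurable
  to match target A_E values. Four linked markers (A, F, G, I by default)
  carry *novel* immigrant alleles; at the others the immigrant haplotype
  carries an existing rare variant (2–6% pre-sweep), reflecting that
  swept alleles were rare or absent before the sweep. Each allele has a
  500-nt sequence template differing at binary-coded SNP sites.
* **Samples.** Generation 0 is drawn at linkage equilibrium from resident
  frequencies (it predates the immigrant). For later time points, each
  haplotype's immigrant/resident lineage is drawn as a **Markov walk along
  the ordered map points**: marginals come from the two-locus model run at
  each marker's inverse-Haldane distance to the suppressor, and adjacent-
  point joints from the exact three-locus model. This preserves the exact
  per-marker marginals and reproduces the model's local LD between linked
  markers; longer-range (non-adjacent) LD is first-order Markov, a mild
  approximation. Non-lineage allele copies are drawn from the pre-sweep
  frequencies. Unlinked markers stay at pre-sweep frequencies. What the
  generator does **not** emulate: drift between time points, spatial
  structure, mutation, genotyping error — so passing recovery tests shows
  the statistics detect the modelled hitchhiking signal at field sample
  sizes, not that they are robust to those real-data complications.
* **Crosses.** Informative backcrosses with phase-known heterozygous
  parents: whole-haplotype maternal transmission (female-informative) or
  per-interval inverse-Haldane recombination without interference
  (male-informative); infected mothers, so sons survive only with the
  suppressor, at 40% viability by default (the empirical estimate).
  Default 600 zygotes ≈ 300 daughters and ~60 surviving sons.

Study sizes used in the shipped tests — 100 seeded replicates at 48
diploids per time point for parameter recovery and null calibration, 5
replicates for LD calibration, B = 199–1000 resamples inside simulation
studies — were chosen to keep the whole suite under a few minutes while
leaving the binomial error bands used in the assertions (3 SD) narrow
enough to be meaningful.

## Numerical and design notes

* All stochastic behaviour flows from explicit integer seeds
  (`numpy.random.Generator`); per-locus sub-seeds are spawned from a
  single `SeedSequence`, so every artifact is bit-reproducible.
* Frequency vectors are renormalized each generation and validated
  (sum 1 ± 1e-9, no negative entries); extinction of either sex raises
  rather than silently producing NaNs.
* The three-locus state enumerates 8 gamete types and 36 unordered
  diplotypes; double recombinants are treated as independent events
  across the two intervals.
* Marker order is taken as given (ordering algorithms are external
  software); recombinant counting assumes the informative parent's phase
  is known from the grandparental cross — phase ambiguity is an input
  error, not inferred away.
* Known limitations: the panmictic, cost-free model overpredicts the
  breadth and magnitude of hitchhiking relative to field observations
  (spatial diffusion, enhancer loci or suppressor costs would all damp
  it); the diffusion loss probability degrades below N ≈ 150; the
  Markov-walk sampler underestimates LD between distant non-adjacent
  marker pairs.
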