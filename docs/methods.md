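# Methods

This note records the statistical models behind `islepop`, the defaults
and their rationale, the synthetic-data generator's assumptions, and the
numerical choices a maintainer would want to know.  Nothing here states a
result the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are unordered diploid allele pairs (integer repeat-size codes)
per individual × locus, with a single missing sentinel; half-missing
calls are collapsed to fully missing because the GENEPOP source format
cannot express them.  At most one locus carries the candidate flag; it is
**never** pooled with neutral loci in any multilocus estimate — every
candidate analysis is single-locus.  Sample filtering drops individuals
missing more than `max_missing_loci` (default 2) *neutral* loci; the
candidate locus does not count toward omission.  GENEPOP population names
follow the format's convention (label of the first individual per POP
block).

## Diversity

* H<sub>E</sub> uses Nei's unbiased estimator (2n/(2n−1))(1 − Σp²);
  H<sub>O</sub> is the heterozygote fraction among valid calls.
* Allelic richness rarefies in **gene copies**: AR_g = Σ_alleles [1 −
  C(N−N_i, g)/C(N, g)].  Private AR follows the rarefaction logic of
  multi-population private-allele estimation: expected count of alleles
  present in the focal g-sample and absent from every other population's
  g-sample.  Note that for g below the other populations' full gene
  counts this is strictly positive even for shared alleles (a finite
  subsample can miss them); the "no unique alleles → private AR = 0"
  identity holds exactly only at full sample size.  When missing data
  leave fewer than g copies at some (population, locus), g is reduced
  per locus to the minimum available count (HP-RARE-style behaviour);
  the per-locus table records the g actually used.
* F<sub>IS</sub> is Weir–Cockerham's within-population f = 1 −
  Σc/Σ(b+c) accumulated over alleles and loci.  The default 95% CI
  resamples **loci** with replacement (999 reps) so the interval
  reflects inter-locus variance, the conventional reading of a
  multilocus bootstrap; an individuals-bootstrap is available via
  `boot_unit`.
* HWE: classical chi-square on genotype classes against allele-frequency
  expectations, df = k(k−1)/2, no continuity correction, no collapsing
  of rare classes.  LD: a permutation G-test on the two-locus genotype
  contingency table per population (one locus's genotypes shuffled among
  individuals), combined across populations by Fisher's method.  This
  replaces the MCMC exact test of the original tool chain with a null
  that is fully specified by the permutation scheme.  All Bonferroni
  denominators count the tests actually performed (non-NA), not the
  nominal grid.

## Differentiation

θ is the Weir & Cockerham (1984) variance-components estimator, summed
over alleles and loci (ratio of sums).  G<sub>ST</sub> and Jost's D use
the Nei–Chesser unbiased Ĥ_S and Ĥ_T (harmonic-mean sample size, H_O
correction); D per locus is (n/(n−1))(Ĥ_T−Ĥ_S)/(1−Ĥ_S) with n
populations.  Multilocus D is the harmonic mean of per-locus D, with
non-positive per-locus values floored at 1e-4 *inside the harmonic mean
only* (reported per-locus values are never truncated; Table-style output
keeps negative estimates and CI bounds as computed).  An arithmetic-mean
combination is available via `d_combine`.

Bootstrap CIs default to resampling individuals within populations
(999 reps, percentile), keeping the locus set fixed as in the usual
pairwise-table presentation; a locus bootstrap is a flag away.  The
resampling unit is genuinely ambiguous in common practice; both are
implemented and the default documented here is the one used throughout.

Genotypic exact tests are Monte-Carlo Fisher tests: null tables drawn by
permuting genotypes between the two populations (fixing margins), with
the rejection region ordered by multivariate hypergeometric table
probability; per-pair p-values combine loci by Fisher's method (defaults:
2000 MC replications, significance p < .001).

## Drift battery

**Effective number of breeders.**  For each locus the mean gene identity
between individuals (Q_b) is compared with the within-individual identity
(Q_w).  For a non-inbred cohort Q_w estimates the parental-pool
homozygosity, so f̂₁ = Σ_l w_l(Q_b−Q_w) / Σ_l w_l(1−Q_w) estimates the
mean kinship of the cohort and N̂_eb = 1/(2f̂₁).  This is a
first-principles molecular-coancestry estimator in the spirit of the
single-cohort breeders method used by the standard N_e software; the
exact published small-sample corrections of that implementation are not
reproduced.  Conventions kept: f̂₁ ≤ 0 reports ∞ (and a configurable
ceiling, default 5000, also maps to ∞); the CI is a delete-one-locus
jackknife; the `infinite` flag additionally engages when the jackknife
CI of f̂₁ reaches 0, i.e. when the data cannot distinguish the
population from an infinitely large one — the situation behind the
"∞" entries such tables print for large mainland samples.  Parameter
recovery is validated on cohorts bred by a known number of monogamous
pairs (kinship 1/4 within couples ⇒ true N_eb = 2 × pairs).

**Bottleneck test.**  For each polymorphic locus (sample 2n genes, k
alleles) the mutation-drift-equilibrium distribution of heterozygosity
conditional on k is simulated with a sequential-construction coalescent
sampler and rejection on the exact allele count.  A recent crash removes
alleles faster than heterozygosity, so observed H_E sits high in that
conditional distribution.  Mutation models: IAM, SMM, TPM (single-step
with probability p_ss = 0.70, otherwise a two-sided geometric multi-step
with variance 30 — the cited software defaults; both configurable).

Three numerical choices matter for calibration, all validated by the
acceptance battery (type-I ≈ 5% within the binomial band over 200
equilibrium SMM datasets):

1. *Probability-scale deviations.*  H|k is skewed, so deviations centred
   at the conditional mean are asymmetric under the null and break the
   Wilcoxon.  The Wilcoxon is therefore run on the rank of the observed
   H within the simulated conditional distribution minus 1/2, which is
   exactly symmetric under the null.  (Mean-centred standardized
   deviations are still reported per locus.)
2. *One θ per population.*  All loci share one mutation-drift regime, so
   θ is tuned once per population to match the mean allele count across
   loci (Ewens-formula start, multiplicative adaptation on pilot
   batches), not per locus — per-locus tuning biases deviations by
   allele count.
3. *Plug-in uncertainty.*  The shared error of θ̂ correlates deviations
   across loci; it is propagated by conditioning on a three-point θ
   mixture spanning ± one standard error of the mean allele count.

Conditioning acceptance below 1% of attempts is flagged per locus.
Fewer than 4 polymorphic loci yields p = NA.  The test is sharply
sensitive to the assumed mutation model: data generated under SMM but
tested under TPM show spurious excess everywhere (TPM's IAM-like
component lowers the conditional H|k), which is worth remembering when
every population in a study "shows a bottleneck".

**Drift regression.**  For each population pair the predictor is the
arithmetic mean of the two populations' diversity values (H_O, H_E or
AR); OLS of pairwise θ and D on it gives the six regressions of the
standard drift figure.  A per-population (duplicated-pair) variant is
available via flag.

## Selection evidence

**Jost's-D envelope.**  Per pair, the neutral loci give D̄ and SEM =
sd/√L; the candidate's single-locus D is classified above/within/below
the band D̄ ± z·SEM with z = 1 by default (the band as drawn in the
standard figure; z is configurable).  Jost's D is used here because
F_ST-analogues are depressed by within-population heterozygosity, which
differs strongly between island and mainland samples.  Note the
geometry: a *neutral* candidate locus is one draw from the per-locus D
distribution, whose spread is ≈ √L·SEM, so even without selection only
~20–30% of neutral candidates land inside a ±1 SEM band.  The envelope
is therefore an effect-size display and a one-sided selection flag, not
a calibrated 95% test; the acceptance battery measures both the
detection rate under island selection and the within-rate of the s = 0
control so the operating characteristics are on record.

**FDist-style scan.**  A finite-island coalescent (100 demes, the
observed number of demes sampled, SMM by default, per-locus θ drawn
log-uniformly on [0.05, 20] to cover the heterozygosity axis) is fitted
so its mean F_ST matches the observed *trimmed* neutral mean (one
iteration of provisional outlier removal, configurable), by bisection on
the scaled migration rate M = 4Nm.  The final cloud (default 50,000
loci; the validation battery uses 5,000) yields conditional quantile
envelopes of F_ST given heterozygosity (k-nearest-neighbour empirical
quantiles); observed loci above/below are positive-selection/balancing
candidates.  This is an approximation of the cited tool's design, not a
clone.  Heterozygosity here is the mean within-population unbiased gene
diversity.

**Island-model conventions.**  The textbook expectation F_ST ≈
1/(1+4Nm) is the many-deme limit; a literal two-deme system equilibrates
near 1/(1+16Nm).  Wherever the closed form is used as an oracle (scan
bisection start, estimator validation) the simulation uses the 100-deme
island model with a subset of demes sampled and low mutation, the regime
in which the formula holds; stepwise-mutation homoplasy additionally
depresses θ at high θ_mut, so oracle checks run at θ_mut = 0.5.

## Synthetic-data generator

Forward Wright–Fisher, non-overlapping generations, random union of
gametes; loci unlinked and simulated independently given the shared
demography (random mating implies no inter-locus associations, which the
LD screen on simulated data confirms).  Mainland demes start from a
shared coalescent equilibrium pool at θ = 4N_max·μ (overridable via
`init_theta`, e.g. for μ = 0 drift oracles); islands are founded by
copying `founder_size` individuals from their source deme at the
configured time and then held at their post-founding size.  Migration is
per-gamete with configurable rates.  Selection at the candidate locus is
genic viability (fitnesses 1, 1+s, 1+2s by favored-allele dosage),
island demes only, s = 0 reducing the candidate to exact neutrality (a
KS property test checks this).  The favored allele is the ancestral
allele nearest `favored_init_freq` (default 0.10 — an uncommon standing
variant, so establishment after the founder bottleneck is probable
rather than certain).

The default scenario: two mainland demes of 5,000; islands founded with
20 individuals, 100 generations ago at post-size 100 (the
longer-isolated island) and 30 generations ago at post-size 250; 14
neutral SMM loci at μ = 5×10⁻⁴ (θ = 10, mainland H_E ≈ 0.78) plus one
candidate locus; weak mainland–mainland migration (2×10⁻⁴); island
selection s = 0.05; present-day samples 347/179/24/38, shaped like the
four-cluster design the pipeline targets.  A `scale` argument shrinks
the mainland size while preserving 4Nμ so the same scenario runs
cheaply; validation and examples run at `scale = 0.1` (mainland N = 500,
μ = 5×10⁻³).  What the generator does **not** emulate: linkage,
overlapping generations, age structure, sex-biased dispersal,
genotyping error and allele dropout — so green tests say the estimators
and their calibration are right under the stated model, not that real
data are free of those complications.

The morphology generator writes seven traits as baseline + sex offset +
optional favored-allele-dosage effect + Gaussian noise, with age drawn
independently (1–14) unless an age slope is configured; it exists to
exercise the ANOVA/correlation machinery, not to model growth.

## Validation battery sizes

Chosen as the smallest sizes that leave the binomial bands meaningful:
estimator nulls 500 splits, island-model check 200 replicate sets of 8
loci (2 demes × 25 individuals), rarefaction enumeration on all fixtures
≤ 10 gene copies, bottleneck calibration 200 equilibrium SMM datasets
(12 loci × 25 individuals, θ = 3, 200 conditional iterations) plus 200
crash datasets (θ = 4 population crashed 20-fold to N = 25 for 15
generations — inside the transient-excess window), N_eb recovery 200
cohorts (10 pairs, 30 offspring, 14 loci), envelope experiment 100
scenario replicates at scale 0.1 for s = 0.05 and s = 0, outlier-scan
self-consistency 200 neutral loci against a 5,000-locus cloud.

## Known limitations

* The N_eb estimator is a re-derivation, not a line-by-line port of the
  published single-cohort method; absolute values can differ by a few
  percent from that software (recovery is validated to ±25% at N_eb=20).
* The bottleneck test's power under SMM with high heterozygosity is
  modest (≈0.35–0.45 in the validation design) — an intrinsic property
  of the heterozygosity-excess approach, not an implementation artifact.
* The outlier scan approximates the cited tool (jump-chain island
  coalescent, kNN envelopes); its false-positive rate is validated, but
  per-locus verdicts on real data will not match that tool decision for
  decision.
* Exact (MCMC) HWE tests, gametic-phase LD, R_ST, AMOVA, temporal or
  LD-based N_e, and Bayesian outlier methods are out of scope.
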