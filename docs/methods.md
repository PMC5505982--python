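# Methods

This note records the statistical models implemented in `pstfst`, the
choices made where the methodology was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Neutral divergence

**Weir–Cockerham θ.** For each allele at each locus the three variance
components *a* (among pools), *b* (among individuals within pools) and *c*
(within individuals) are computed from per-pool allele frequencies,
observed heterozygote frequencies and sample sizes. The multi-locus
estimator is the ratio of sums, θ = Σa / Σ(a+b+c), over alleles and loci —
not an average of per-locus ratios, which would be biased for weakly
polymorphic loci. Missing genotypes are handled complete-case per locus
(the standard treatment); a pool contributes to a locus only if it has at
least one called genotype there. Small negative θ values are legitimate
estimator behaviour and are not clipped (only the theoretical upper bound
of 1 is enforced). 95% CIs are percentile bootstrap over loci. With six
loci the bootstrap support has at most 462 distinct resamples, so these CIs
are coarse; that is a property of any six-locus study design, not of the
implementation.

**Exact genotypic differentiation and pool merging.** Each pool pair is
tested per locus on the genotype × pool contingency table under the
fixed-margins null. Rather than enumerating the table network, the null is
sampled directly: one pool's genotype-category counts are multivariate
hypergeometric draws given the margins (equivalent to permuting pool
labels). The statistic is the table probability; p is the +1-smoothed
proportion of sampled tables no more probable than the observed one, so p
is never 0 and the test is slightly conservative. Loci combine by Fisher's
method. Pairs with combined p above the merge threshold (default 0.001) are
joined, and merging is the transitive closure of the non-significant graph
— the closure rule matters only for non-transitive outcomes, which the
threshold makes rare but possible. The genotypic (not allelic) table is
used; calibration tests show correct-to-conservative type-I error, and
power analyses during development showed the allelic variant would be
substantially more powerful. The genotypic test is retained because it is
the field-standard default for this analysis.

**Null alleles.** A per-pool, per-locus EM estimate under Hardy–Weinberg
with one unobservable allele: apparent homozygotes are mixtures of true
homozygotes and visible/null heterozygotes, and missing genotypes are
treated as null homozygotes (the Dempster-EM convention of microsatellite
practice). If genuine technical missingness is present this overestimates
the null frequency; the estimate should be read as an upper bound in that
case.

**Population-specific F_ST.** The hierarchical model: at each locus, pool
*i*'s allele frequencies are Dirichlet-distributed around the ancestral
frequencies with concentration θᵢ = (1 − Fᵢ)/Fᵢ. Pool frequencies are
integrated out analytically, leaving a Dirichlet-multinomial likelihood for
the observed allele counts given {Fᵢ} and the ancestral frequencies — a
collapsed sampler, which mixes better than sampling pool frequencies
explicitly. Fᵢ gets a uniform (0, 1) prior and a logit random-walk update;
each locus's ancestral frequency vector gets a flat Dirichlet prior and a
Dirichlet proposal centred on the current value (concentration 200), with
the Metropolis–Hastings correction. Defaults: 50 000 iterations, 10 000
burn-in, thinning 10. Convergence is monitored by a split-chain
Gelman–Rubin statistic per pool (threshold 1.1); non-convergence flags the
result rather than suppressing it. At least three pools are required —
with two, pool effects and ancestral frequencies are not separable. The
environmental-regression layer found in full Bayesian F_ST software is out
of scope here.

## Phenotypic divergence

**PERMANOVA.** One-way: the Anderson (2001) partition computed directly
from squared distances (SS_total from all pairs, SS_within from
within-group pairs), pseudo-F = MS_B/MS_W, p by unrestricted permutation of
group labels with +1 smoothing. Two-way crossed: the Gower-centred matrix
is partitioned sequentially by hat matrices of the nested design matrices;
main effects are tested by permutation of raw observations, the interaction
by permutation of residuals under the main-effects model (Freedman–Lane) —
the scheme recommended for crossed designs when software manuals leave it
unspecified. On univariate data both reduce exactly to classical ANOVA F
statistics, which the tests verify against closed-form and `statsmodels`
oracles. Post-hoc pairwise tests report t = √pseudo-F on each pair's
sub-matrix, unadjusted by default (a Šidák option exists) since multiplicity
handling is conventionally reported alongside, not folded into, these
tables. Degenerate all-identical data yield an undefined F, reported as NaN
with p = 1.

**P_ST.** σ²GW = MS_W; σ²GB = (MS_B − MS_W)/n0 with negative estimates set
to zero; n0 is the unbalanced-design weighted sample size (equal to n for
equal pools and never exceeding max nᵢ). P_ST = r·σ²GB/(r·σ²GB + 2σ²GW)
with r = c/h² = 1 by default and a {0.5, 1, 2} sensitivity sweep available.
The 0/0 case returns 0 with a flag. The bootstrap resamples colonies with
replacement **stratified within genetic pool**, preserving the nᵢ; without
stratification a replicate can lose a pool entirely and the design becomes
inestimable. The point estimate is the bootstrap median; the CI bounds are
the 25th and 975th sorted values at 1000 replicates (percentile
interpolation otherwise). The inner PERMANOVA's permutations do not affect
mean squares, so the default path computes the mean squares directly from
the day-vectors via the Euclidean identity; a `fast=False` path runs the
full permutation PERMANOVA per replicate and is verified to give identical
mean squares. Because the bootstrap is stratified within pools, the CI
reflects within-pool sampling noise only — it does not propagate the
evolutionary "draw" of the pool effects themselves. Coverage statements in
the tests therefore use panels whose realized between-pool variance is
fixed by construction.

**Comparison.** Mantel r is the Pearson correlation over the 15
upper-triangle pairs with simultaneous row/column permutation of one
matrix; one-sided (positive association) by default, matching the
directional hypothesis, with a two-sided option. CI overlap uses closed
intervals (touching endpoints overlap — conservative toward "no
difference"). The Spearman correlation between population-specific F_ST and
final-day necrosis uses average ranks and an exact permutation p-value for
up to 8 pools (the asymptotic approximation is unreliable at n = 6);
two-sided by default, as in the standard correlation-test convention.

## Thermal statistics

Daily climatology computes daily means first, then per-julian-day mean and
SD across years, with Feb 29 folded into day 59 so every year contributes
365 days. The warm period is July 1–October 31 inclusive; warm-period and
extreme-tail (≥ the 90th percentile of pooled warm-period records)
statistics are computed on raw hourly records, all years pooled, with
type-7 (linear interpolation) quantiles. Between-regime comparison is a
tie-corrected Kruskal–Wallis test on hourly warm-period records, with Dunn
pairwise z-tests under a Šidák family-wise adjustment
p_adj = 1 − (1 − p)^m.

## Synthetic data

Genotypes follow the Balding–Nichols model: per locus, ancestral
frequencies from a symmetric Dirichlet(1); pool frequencies from
Dirichlet(θᵢ·p_anc) with θᵢ = (1 − Fᵢ)/Fᵢ (Fᵢ = 0 copies the ancestral
frequencies exactly); genotypes under within-pool Hardy–Weinberg. Null
alleles, when requested, act per allele copy: null homozygotes become
missing, null heterozygotes apparent homozygotes.

Necrosis trajectories are cumulative non-negative gamma increments around a
monotone logistic baseline (tissue necrosis is irreversible), shifted by a
pool effect (drift-linked slope × Fᵢ plus Normal between-pool noise) and a
colony effect, clipped to [0, 100]; Control colonies are generated at zero.
The increment coefficient of variation (default 0.5) is the one noise knob
the trajectory model needs; setting it to 0 gives deterministic increments,
used wherever an exact between/within variance ratio must hold.

Default study conditions: six genetic pools × 30 colonies × six loci with
12 alleles each; drift profile F = (0.04, 0.05, 0.05, 0.06, 0.11, 0.16)
(mean 0.078 — global differentiation near the mid-0.07 range typical of
fragmented gorgonian populations, with two strongly isolated pools);
necrosis slope 300 %/unit-F, between-pool sd 2 %, within-pool sd 10 %. Two
properties drove the profile shape, both fixed before the test suite was
frozen: (i) with evenly spaced Fᵢ and a deterministic slope, pairwise
phenotypic distance is exactly uncorrelated with pairwise genetic
divergence over the 15 pairs, so a drift-dominated regime requires an
uneven profile (a few strongly drifted pools), and (ii) all six pools must
be separable by the genotypic exact test at the 0.001 merge threshold at
these sample sizes. Temperature series are a seasonal sinusoid (annual mean
17 °C, amplitude 4 °C, peak in mid-August) with per-site offsets, a linear
depth attenuation (3 °C at 40 m) and 0.4 °C hourly noise over 3 years.

What passing tests on these data do **not** show: the generator has no
selection term, no isolation-by-distance spatial structure, no mutation
model (allele identities are exchangeable), no temporal autocorrelation in
temperature beyond the seasonal cycle, and independent loci — so the tests
validate estimator correctness and the drift-regime logic, not robustness
to linkage, selection at the trait loci, or real mortality-event dynamics.

## Problem sizes and numerics

Heavy checks are run at sizes chosen to keep Monte-Carlo error well below
the tolerances asserted: θ recovery over 100 replicates (4 pools × 50,
8 loci); the Balding–Nichols ordering oracle over 60 replicates (3 pools ×
120, 10 loci); rank recovery of population-specific F_ST at 3 pools × 200
and 12 000 MCMC iterations; P_ST CI coverage over 50 replicates at n_boot =
200 with 6 pools × 80; type-I calibration of the one-way PERMANOVA and the
exact test over 500 null replicates each (the binomial 95% band around
α = 0.05 is the acceptance region). Permutation p-values use +1 smoothing
throughout; permutation and bootstrap streams derive from per-stage child
seeds of one master seed, so adding a stage never perturbs another's
output. Tie comparisons in permutation tests use a 1e-9 absolute tolerance
on the statistic.

## Known limitations

* Six-locus bootstrap CIs for θ are coarse (few distinct resamples).
* The stratified P_ST bootstrap understates total uncertainty when the
  number of pools is small (see above); this mirrors the printed procedure
  it implements.
* The exact-test/merge step loses power for weakly drifted pools at 30
  colonies per population; merged pools are an honest outcome, and the
  pipeline degrades gracefully (comparison stages require ≥4 pools and are
  skipped with a marker file otherwise).
* The null-allele EM conflates technical missingness with null homozygosity.
* The population-specific F_ST sampler omits any environmental covariate
  layer by design.
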