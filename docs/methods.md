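# Methods

This note documents the models, estimators, thresholds and numerical
choices implemented in lumenstrain, and what the synthetic benchmark does
and does not establish.

## The generative model behind the synthetic cohort

The generator emulates a gnotobiotic colonisation experiment: a single
human inoculum community colonises 8 mice housed in 3 cages (3/2/3 mice),
and each mouse is sampled at five gut regions; the inoculum is a 41st
sample. All quantities flow from one integer seed through named streams
(one per stage and species, derived via a stable hash into a SeedSequence
spawn key), so adding a species or stage never perturbs existing draws.

**Strains and genotypes.** Each species carries 1–3 strains. Any two
strains differ at a configured number of SNVs (default 2000, matching the
empirical 10³–10⁴ between-host scale). Two-strain genotypes differ at
exactly that many sites. Three-strain genotypes are laid out on the rooted
tree ((A,B),C): private mutations on each leaf branch plus shared mutations
on the internal branch, with branch site counts solved so all three
pairwise distances equal the configured divergence (hence the requirement
that it be even). The shared-by-two class surfaces at allele frequency
1 − f_C and is collapsed onto the private-to-C class by the phaser's
polarisation — which is exactly why three strains yield three (not four)
clusters. Each site's ref/alt labelling is flipped with probability 1/2 to
emulate arbitrary reference-genome polarisation. Optional "intra-strain"
sites sit at a constant low frequency (default 0.02) in every sample; they
mimic unlinked within-population variation and must be discarded by the
phasing filters.

**Strain frequencies.** Frequencies are hierarchical on the log-odds
scale: for two strains, logit f = logit f_inoculum + cage + mouse + region
effects, each drawn independently as N(0, σ²) at its level. For three
strains the effects act on log-frequencies with renormalisation (the
two-strain case is then logit-normal exactly; the K = 3 case is its natural
simplex generalisation). With all σ = 0 every sample reproduces the
inoculum frequencies. A `uniform` frequency model (each mouse sample's
strain frequency i.i.d. Uniform(0.2, 0.8)) is provided for
frequency-recovery benchmarking, where a wide, known spread of truths is
wanted. No explicit migration model is implemented: the region effect is a
phenomenological stand-in, not a mechanistic flow model.

**Observations.** Per site and sample, depth is Poisson (or negative
binomial with dispersion r, since real shotgun depth is overdispersed) with
mean = mean_depth × a per-sample batch multiplier (emulating a
deeper-sequenced batch, labelled `deep` in the sample sheet). Alternative
reads are Binomial(D, p(1−2ε)+ε) where p is the strain-weighted true
frequency and ε a per-read miscall rate. A species can fail to colonise a
mouse (dropout), zeroing its depth in that mouse's samples. Species
abundances are log-normal with per-sample noise, renormalised over
colonising species; they feed only the community-diversity summaries.

**Planted sweeps** are extra sites on the background of one named strain
with configured start (≤ 0.2) and end (≥ 0.8) frequencies and an inoculum
frequency (0 = de novo; > 0 = standing variation). Scopes: all regions of
one mouse, a single region, or one mouse in each of two cages (parallel).

What the benchmark does **not** show: performance under read-mapping
artifacts, reference bias, recombination, strain numbers above three,
genuinely overlapping strain trajectories, or compositional coupling
between species abundances and SNV depth. Passing tests demonstrate the
statistics are implemented correctly and behave as designed under their own
assumptions, not that those assumptions hold in any particular real
dataset.

## Coverage filters

A (species, sample) is analysed only when mean depth over protein-coding
sites is ≥ 5× and ≥ 40% of sites have nonzero coverage (the breadth rule is
applied per sample; a per-species variant would be a one-line change and
the choice is exposed by calling the filter per sample set). When no coding
annotation exists the mean is over all sites and the report flags it.
Per-site coverage must lie in the closed band [0.3×, 3×] of the sample mean
(computed over all sites, after the sample filter and before any other
masking). Depth thinning of a deep batch draws, per site, the kept
alternative reads from a hypergeometric law — i.e. actual reads subsampled
without replacement to the reference samples' per-site median depth; cells
at or below target, and sites whose reference median is zero, are
untouched.

## Nucleotide diversity

π is the expected probability that two reads drawn without replacement at a
site carry different alleles; the D/(D−1) factor makes the per-site
contribution an unbiased estimate of heterozygosity 2p(1−p), which the test
suite verifies directly at p = 0.3, D = 10. Sites with depth < 4 are
excluded and |G| counts the usable sites, so π is undefined (NaN, never 0)
when |G| = 0. The 0.3×/3× band is also applied by default
(config-switchable) since it is a global mapping-artifact guard. The
500,000-usable-site reporting rule is exposed as `min_pi_sites` and must be
scaled down for fixture-size genomes (scenarios use 100). A species' π is
reportable when the inoculum and at least three mouse samples from at least
two mice are valid. The within-mouse variance of π is the mean over mice of
the variance across that mouse's regions; the between-mouse variance is the
mean over regions of the variance across mice (sample variance, ddof 1).
Shannon diversity uses natural log; Bray–Curtis is Σ|a−b|/Σ(a+b); region
contrasts average the small-intestinal (duodenum, jejunum, ileum) and
large-intestinal (cecum, colon) values per mouse and use an exact paired
two-sided Wilcoxon signed-rank test, dropping (never imputing) mice missing
a whole group.

## Strain phasing

Sites enter phasing when, in ≥ 20% (inclusive) of the samples where the
species is detected, they have depth ≥ 10 and both alleles supported by
≥ 4 reads — fixed sites would otherwise cluster at frequency 0/1 and
rare-variant noise would seed low-frequency clusters. The pair distance is
averaged over the intersection of samples where *both* sites have depth
≥ 10; at least `min_overlap` = 3 shared samples are required for an edge,
preventing spurious zero-sample links. A per-sample term with zero
denominator has zero numerator (both frequencies 0, or both 1) and
contributes 0. The polarised distance is min(d(f_i, f_j), d(f_i, 1−f_j)),
making d invariant to flipping either trajectory.

Greedy clustering: edges at d < 3.5 (strict); the focal SNV is the
max-degree node, ties broken to the lowest site_id; members are the focal
plus its neighbours; the 25% connectivity prune runs once, visiting members
in site_id order against the shrinking member set (the focal is exempt);
clusters below `min_cluster` stop the loop. These tie-break and iteration
semantics are deliberate fixed choices — the procedure is order-dependent,
so sites are always processed in sorted site_id order, which makes output
invariant to input row order. A brute-force plain-Python re-implementation
with the same rules serves as an oracle in the tests on ≤ 50-SNV instances.
The `mean_focal` mode seeds a single cluster from the per-sample mean SNV
frequency (with mean depth standing in for the focal's depth) for the
pathological case where high per-SNV variance splits one mutation class in
two; the trigger is left to the analyst — an automatic trigger would need a
reliable between-cluster trajectory-correlation heuristic we have not
validated.

Strain frequencies: with one cluster the two strains are (f̄, 1 − f̄),
f̄ the mean polarity-corrected frequency over cluster SNVs with depth ≥ 10
in that sample; a sample is reported only when every cluster has ≥ 100 such
SNVs. With ≥ 2 clusters (the three-strain regime) per-class mean
frequencies are emitted but flagged `frequencies_identified = False`: the
mapping from mutation classes to strain frequencies is not identified
without further assumptions, and we do not guess. CIs are percentile
2.5/97.5 over 1000 i.i.d. resamples of 100 SNVs. The fixed 100-SNV resample
is kept as specified even for larger clusters, which makes the interval
conservative there; the CI-coverage benchmark therefore uses 100-SNV
clusters, where the nominal level is exact. When clustering yields nothing
but the inoculum still holds ≥ 1000 polymorphic SNVs (depth ≥ 10, minor
≥ 4 reads) — e.g. the minor strain never colonised — two inoculum strains
are reported at (mean, 1 − mean) of those SNVs, each polarised to its minor
inoculum allele so the first strain is the minor lineage.

## Variance partition of strain frequencies

The response is the CLR of the two-part composition (f, 1−f), which
reduces to 0.5·ln(f/(1−f)), with f clamped to [10⁻⁶, 1−10⁻⁶]. Sums of
squares are sequential (type I) in the fixed order cage → mouse → gut
region — mouse is nested in cage, so this order attributes shared
cage/mouse variation to cage first; fractions of total SS are reported with
the residual as remainder. Eligibility requires detection in ≥ 2 cages
(each with ≥ 2 mice), ≥ 2 mice (each with ≥ 2 regions) and ≥ 2 regions
(each in ≥ 2 mice); a zero-variance response is reported as degenerate
rather than partitioned.

## Quasi-phasing and SNV changes

A sample is QP when its median site depth (within the coverage band) is
≥ 20 and its intermediate-frequency SNV count (0.2 < f < 0.8 at depth
≥ 20) is at most 10% of the species' expected between-host divergence. That
calibration cannot come from mice sharing one inoculum; synthetic runs take
it from the configured inter-strain divergence, and real-data runs must
supply a per-species table (`--calibration`). The phased genotype assigns
the alternative allele where f ≥ 0.8 and the reference where f ≤ 0.2, at
depth ≥ 20.

Changes between QP pairs track the alternative allele in both samples (so
detection is symmetric in sample order): a change needs f ≤ 0.2 on one side
and f ≥ 0.8 on the other at depth ≥ 20 in both. For same-mouse pairs the
two depths must also agree within a factor of three — coverage should be
nearly constant within a mouse, so large ratios flag artifacts; the rule is
scoped to within-mouse pairs by default with a switch to extend it. Pairs
with > 50 changes are excluded as carrying distinct inoculum strains.
Unique changes deduplicate on (species, site), keeping the largest
frequency contrast; standing-variation status requires inoculum depth ≥ 20
(below that it is "unknown", never "false"); a change is parallel when its
allele reaches f ≥ 0.8 in mice of ≥ 2 cages. Rate CIs resample 100 pairs
(possibly across species) 1000 times per category and take the 2.5/97.5
percentiles of pooled changes/loci; primary categories (within host,
between hosts, inoculum vs host) are mutually exclusive, and the
within-cage comparison is the different-host same-cage subset of
between-host pairs.

## Problem sizes and defaults used in the shipped benchmarks

Scenario fixtures use one to five species with 2000–4000 divergent SNVs on
10⁵ bp genomes at 30–50× depth, per-read error 0–0.002, and fixture-scaled
gates (`min_cluster` 400–500, `min_pi_sites` 100); these sizes were chosen
so each benchmark represents its genome-scale analogue faithfully while a
full suite run completes in about a minute per heavy check on one core.
Frequency recovery uses 20 independent cohorts of 20 samples; CI coverage
uses 200 replicates; the greedy-vs-brute-force equivalence suite uses 100
random ≤ 50-SNV instances. All thresholds default to their genome-scale
values in `RunConfig` and are recorded, with a config hash, in every run's
outputs.

## Known limitations

- No read-level simulation (FASTQ), recombination, assembly, HGT, or gene
  copy-number analysis; synonymous/nonsynonymous labels are assigned by the
  simulator, not by annotation.
- Three-strain frequency deconvolution is deliberately not attempted.
- The bootstrap is i.i.d. over SNVs; block resampling along the genome
  (for linked noise) is not implemented.
- The ANOVA treats factors as crossed fixed effects in a fixed sequential
  order; a mixed-model treatment of the nesting is out of scope.
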