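# Methods

This note documents the statistical models behind each module, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that matter for
reproducibility.

## Splicing quantification

Only junction-spanning reads are modeled; exon-body coverage is out of
scope. A skipped exon is supported by two inclusion junctions but one
exclusion junction, so raw junction counts are normalized by these
effective lengths (SE 2:1, MXE 2:2) before forming PSI. A5SS, A3SS and RI
events are parsed and counted in prevalence summaries but excluded from
inference: they are rare and less often translated into functional
isoforms. Samples with zero junction reads at an event get a missing PSI,
never an exception.

**Coverage filter.** An event is testable when both the inclusion and
exclusion junction counts are at least `min_junction_reads` (default 20)
in at least `min_fraction` (default half) of the samples of *each* sex.
An event is called "alternatively spliced" in a group when 0 < PSI < 1 in
strictly more than half of that group's individuals.

## The beta-binomial likelihood-ratio test

Per event, the inclusion junction count k out of n junction reads is
modeled beta-binomial with proportion q (the effective-length-adjusted
transform of PSI) and intraclass correlation ρ. The test compares a
shared q (H0) against sex-specific q (H1); 2Δlogℓ → χ²(1); BH-FDR across
events. The significance rule is FDR < 0.05 AND |ΔPSI| ≥ 0.1, the
fold-change-like guard inclusive at exactly 0.1. For gene-set comparisons
against differential expression an alternative rule (FDR < 0.05 and
|log2 PSI fold change| ≥ 1) is provided so both sets are defined at
equivalent stringency (`psi_log2fc_significance`).

**Dispersion.** ρ is a per-event method-of-moments estimate shared by both
groups. Two moment estimators exist: residuals around each group's mean
(which ignores the between-group contrast and leaves the plug-in LRT
anticonservative at n = 5 + 5) and residuals around the pooled mean (which
absorbs the tested contrast and is conservative). The implementation uses
their average, with exact finite-sample degrees-of-freedom corrections in
both; simulation at the study's sample sizes shows type-I error within
[0.03, 0.07] at nominal 0.05 under a beta-binomial null (ρ = 0.05,
coverage 100, 1000 events). Events where the fit is degenerate (all-zero
or saturated counts) fall back to the binomial (ρ = 0).

**Optimization.** The proportion MLE is found by vectorized golden-section
search on the logit over [−14, 14] (80 iterations, interval < 1e−10),
simultaneously for all events; there are no per-event Python loops, which
is what keeps the 100-replicate randomization procedure at seconds per
replicate for thousands of events.

## Gene expression

Gene counts are sums over constitutive exons only, so splicing changes
cannot leak into expression calls; genes losing all exons are dropped.
Genes must reach 1 log2-CPM in at least half the individuals of both
sexes (pseudo-count 0.25 on CPM). Normalization is TMM: the reference is
the sample whose 75th-percentile count fraction is closest to the mean;
M-values are trimmed 30% from each tail and A-values 5% from each tail by
rank (the double-trim convention of the standard implementation, which
this module reproduces to ~1e−6 on a 50-gene panel); the factor is the
precision-weighted mean log-ratio, rescaled so factors have geometric
mean 1.

The sex-differential test is a negative-binomial LRT with a common
dispersion α (var = μ + αμ²) estimated by a depth-corrected moment
estimator: for depth-normalized counts, Var = μ·E[1/d] + αμ², so
(s² − μ·mean(1/d))/μ² estimates α per gene; the pooled value is a
1%-trimmed mean over genes with normalized mean > 5, per sex. A gene is
sex-biased when |log2FC| ≥ 1 and FDR < 0.05, log2FC taken from normalized
CPM means with a pseudo-count.

## Isoform specificity (τAS)

For one gene and sex, each retained splice site contributes two isoforms
with supports x_i (inclusion) and y_i (exclusion) summed over that sex's
individuals. All supports are normalized by the *gene-and-sex* maximum —
a per-site maximum would force a zero term at every site and could never
reach the documented boundary values — and

    τAS = Σ_i [(1 − x̂_i) + (1 − ŷ_i)] / (n − 1),  n = 2 · n_sites.

The denominator n − 1 with n counted as isoforms (not sites) is the only
reading consistent with both boundary anchors: a single always-expressed
isoform at one site gives (0 + 1)/1 = 1, and even representation gives 0.

Sites must carry ≥ 20 inclusion and exclusion reads in at least half the
individuals, within either sex or pooled. Because detection power scales
with expression, the more highly expressed sex's counts are scaled down
to the other sex's per-gene total using exact real ratios (integer
rounding would introduce a direction-dependent bias). An optional
sensitivity variant divides each sample's counts by its library size
first. Male-female differences within expression-bias classes are tested
with paired Wilcoxon signed-rank tests; classes under 5 genes report a
missing p.

Tissue specificity τ uses the same functional form over a genes × tissues
expression matrix, τ = Σ(1 − x̂)/(T − 1); the module consumes an external
per-gene τ table (e.g. derived from a multi-tissue expression compendium)
rather than recomputing it from raw data.

## Morph intermediacy randomization

Each of (default) 100 replicates draws 3 dominant males and 3 females,
calls differential splicing on that discovery subset, orients every
discovered event so the female-biased direction is positive ("higher =
more feminized"), and compares event-wise mean oriented PSI between
held-out groups with Wilcoxon rank-sum tests at α = 0.05: subordinates vs
held-out dominants (one-sided, subordinate higher), subordinates vs
held-out females (one-sided, lower), and dominant-vs-dominant /
female-vs-female held-out splits as two-sided controls. Discovery and
evaluation samples are disjoint by construction (asserted per replicate);
replicates that discover no events count as non-significant. Sampling is
without replacement within a replicate and independent across replicates
from one master seed. Event-level (not gene-level) PSI is used
throughout.

## Overlap statistics and clustering

The representation factor is observed/expected overlap with expected =
|DSG|·|DEG|/n; under-enrichment is the lower tail of the exact
hypergeometric distribution, BH-adjusted across the species × tissue
family. The k-way ortholog overlap uses the exact distribution of the
intersection of independent uniform fixed-size draws, built by iterated
hypergeometric convolution (the intersection of the first j sets is
uniform given its size), with a Monte-Carlo mode as cross-check. The
default universe is the genes expressed (testable) in all species.

Sample clustering is average-linkage on Euclidean distances over per-gene
mean PSI, with support per clade as the fraction of feature-bootstrap
trees containing it. Plain bootstrap proportions are reported rather than
multiscale-corrected values: the claim being checked is qualitative
(which clades are stable), and ordinary support is sufficient and simpler
to interpret. Trees are written as Newick with support as internal node
labels.

## Population genomics and molecular evolution

Hudson's FST per site uses the small-sample-corrected numerator
(p1 − p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1) over denominator
p1(1−p2) + p2(1−p1); the per-gene value is the ratio of sums across
sites (never a mean of per-site ratios, which is badly behaved at
low-diversity sites). Monomorphic genes are missing, and slightly
negative values are expected and retained when frequencies are equal.
Tajima's D uses the standard constants from the number of chromosomes;
S = 0 yields a missing D.

The architecture test classifies genes as candidates for sex-differential
selection when FST exceeds its 75th percentile AND D is below its median
(both quantiles configurable and recorded in output headers — the source
analyses do not print their thresholds), after removing sex-differentially
expressed genes, genes whose annotation mentions "immune" or "MHC", and
genes under 2 log2-CPM; a χ² test with continuity correction scores the
2×2 table against differential splicing.

Class-level dN/dS is (ΣNdN/ΣN)/(ΣSdS/ΣS) after excluding genes with
dS > 2 (mutational saturation); 95% CIs are percentile bootstrap over
genes (default 1000 replicates) and class contrasts are label-permutation
tests (default 1000). A linear model of per-gene dN/dS on class plus log
length and log expression, with an ANOVA F-test for the class term,
checks that class differences survive covariate control.

## Synthetic data

The generators mirror the structure of a three-species bird study: ~5
individuals per sex, a turkey-like species with 5 dominant males, 2
subordinate males and 5 females in the gonad, a minority of events with
sex-biased PSI, and gene classes differing in expression bias and
evolutionary rate.

- **Splicing:** baseline male PSI ~ Beta(2, 2) (the empirical PSI
  distribution is unknown; this is an explicit, parameter-exposed
  assumption); biased events offset the female PSI by ±δ clipped to
  [0.05, 0.95]; subordinate PSI is exactly λ·male + (1−λ)·female. Total
  junction reads per sample are Poisson(coverage); inclusion counts are
  beta-binomial on the effective-length-adjusted proportion — the same
  family the test assumes, giving a self-consistent null for type-I-error
  checks.
- **Expression:** negative-binomial counts with symmetric log2FC splits
  for biased genes, log-normal library sizes to exercise normalization,
  and optional Dirichlet tissue profiles.
- **Allele counts:** neutral 1/i site-frequency spectrum; differentiated
  genes place a ±d/2 intersexual offset on a configurable fraction of
  sites (interior frequencies, as a large offset demands) while their
  remaining sites can be skewed toward rare variants (weight ∝
  1/i^(1+skew)) — the combination that produces the elevated-FST/low-D
  architecture the selection tests look for; an intersexual frequency
  offset alone forces intermediate frequencies and hence *high* D.
- **dN/dS:** site counts at the canonical ~3:1 nonsynonymous:synonymous
  ratio of the simulated CDS length, Poisson substitution counts with
  dN = ω·dS per class, and a small dS > 2 fraction to exercise the
  saturation filter.

What the generators do **not** emulate: mapping and alignment artifacts,
shared splicing regulators (events are independent given the truth
table), linkage between sites, phylogenetic correlation among genes, and
any coupling between the splicing, expression and popgen layers beyond
what a test plants explicitly. Passing tests therefore demonstrate the
estimators' statistical behavior under the stated models, not robustness
to real-data pathologies.

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale: the
randomization procedure at 2000 events × 100 replicates, calibration
checks at 1000–2000 events, bootstrap coverage at 200 scaled-down
replications. These sizes give Monte-Carlo error comfortably inside the
asserted bands while keeping a full run in minutes on one CPU. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
pipeline outputs embed seed, version and thresholds in their headers and
reruns are byte-identical.

## Known limitations

- The LRT's χ²(1) reference is asymptotic; at 2–3 samples per group
  (e.g. the 3v3 discovery subsets) it is approximate, which is why the
  randomization procedure judges only held-out samples.
- Common (not tagwise) dispersion in the expression test; no GLM designs
  or batch correction.
- The beta-binomial model treats samples as exchangeable within sex; no
  paired or hierarchical designs.
- Tissue τ is consumed, not computed from raw multi-tissue data.
- The popgen module starts from allele counts; genotype-likelihood
  uncertainty is upstream and out of scope.
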