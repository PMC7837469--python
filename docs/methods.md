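# Methods

This note documents the statistical model behind `gsca`, the numerical
choices made where several were defensible, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Haplotype-matching genotype likelihoods

Low-coverage reduced-representation reads cannot support per-SNP genotype
calls in a species as polymorphic as *Mimulus guttatus*. Instead, each
read-pair is compared against the K distinct genic haplotypes of its gene
set (derived from a panel of sequenced inbred lines from the same
population), and the plant-level likelihood of every unordered diploid
genic-genotype [i, j] is a product of per-read mixture terms

    U[i,j] = ∏_r ( ε^h(r,i)/2 + ε^h(r,j)/2 ),

with h(r, k) the mismatch count of read r against haplotype k. Two points
about this form:

* **Matching sites contribute a factor of 1**, not (1−ε). The full
  Bernoulli form ε^h(1−ε)^(s−h) is available behind `bernoulli=True`; at
  ε = 0.005 and a median of 6 SNPs per read-pair the two differ by a
  genotype-independent factor of about (1−ε)^s per read, which cancels in
  every frequency estimate and test. The simpler form is the default
  because it is the canonical statement of the method.
* **ε defaults to 0.005**, the empirically appropriate aggregate of
  sequencing and alignment error for the target data type. It is a tuning
  constant, not an estimated parameter.

Everything is computed in log space with per-read scaling, so arbitrary
mismatch counts cannot underflow. A plant × gene-set table is flagged
*unknown* when even its best genotype implies more than two mismatches per
read-pair on average (max log U < RP · 2 ln ε); such tables are treated as
flat. The published description of the method says only that wholly
inconsistent plants are "treated as unknown"; the 2-mismatch rule
implements that intent without a hard zero, and at realistic error rates it
essentially never triggers for genuine panel members.

## Gene sets, haplotypes, and SNP thinning

Genes separated by at most 100 bp (or overlapping) are merged into gene
sets by transitive closure; a gene set is the unit of non-recombining
haplotype inference. Identical panel lines collapse to one haplotype with
frequency Q_k = multiplicity/lines. SNPs whose haplotype-indicator vectors
δ are identical *or complementary* are thinned to the 5′-most
representative: a complemented indicator induces the same bipartition of
haplotypes and therefore identical genotype likelihoods. Strict
identity-only thinning is available via a flag. SNPs monomorphic in the
panel are dropped — no frequency contrast is estimable for them. Internal
coordinates are 0-based half-open; GFF3 conversion happens at the I/O
boundary.

## Family likelihoods and the model hierarchy

The data likelihood is a product over families (Hardy–Weinberg prior for
the maternal genotype under cohort-reweighted haplotype frequencies Q\*,
the mother's U, and per-offspring transmission terms). Cohort frequencies
enter only through the proportional reweighting
Q\*_k = Q_k p\*/p (reference class) and Q_k(1−p\*)/(1−p) (alternative
class), which preserves relative frequencies within allele classes.

For outcrossed offspring the sire-allele frequency p_M enters linearly:
V = p_M T1 + (1−p_M) T2, where T1/T2 aggregate the offspring's genotype
likelihoods over reference-/alternative-class sire haplotypes. They are
computed once per offspring before optimization, which makes each
likelihood evaluation O(F · G) for F families and G = K(K+1)/2 genotypes.
Selfed offspring contribute the Mendelian mixture ¼U_ii + ½U_ij + ¼U_jj and
carry no information about p_M. Offspring whose mating type could not be
classified are treated as outcrossed; misclassification of the ~10% selfed
fraction slightly inflates predicted change but does so uniformly.

The year-2 hierarchy is: H0 (all cohorts share p), H1 (p_A = p_M, p_L
free), H2 (p_A = p_L, p_M free), H3 (all free). This is the unique
assignment that makes the male-selection contrast (H3 vs H1) and the
viability contrast (H3 vs H2) 1-df tests of the named parameters. The
cross-year change test constrains p_A(year 1) = p_Z(year 2) under the null,
with p_Z fitted H0-style from all year-2 cohorts; the year-1 side uses H1
(p_A, p_M free) in both null and alternative, so the contrast isolates the
frequency change itself. A config switch (`year1_model="H0"`) collapses the
year-1 side for sensitivity analysis.

### Optimization

Likelihoods are maximized with Powell's direction-set method on
logit-transformed frequencies (start at the panel frequency; restarts from
0.25/0.75 on failure; ftol 1e-9). Estimates are clamped to
[1e-6, 1−1e-6] and p-values floored at 1e-300. Nested fits that come out
inverted beyond 1e-9 (an optimizer artifact) trigger a warm-started refit
of the more general model; LRT statistics are floored at zero. A
Nelder-Mead polish of Powell solutions on 100 random replicates improved
log-likelihoods by less than 2e-12, so the optimizer is not a source of
miscalibration.

## Predicted and observed Δp

Male selection predicts Δp = (p_M − p_A)/2 (diploid zygotes are half male
gametes); viability selection predicts Δp = (1 − α)(p_A − p_L), from
p_Z = α p_A + (1 − α) p_L with survival fraction α. The default α = 0.7
comes from the field survey anchor (700 of 1000 marked seedlings
flowering), giving the 0.3 coefficient; it is configurable. The observed
Δp is p_Z(year 2, H0 fit) − p_A(year 1, H1 fit) — the pooled H0 frequency
is used because it is always intermediate to the more elaborate models'
estimates.

Genome scans report at most one SNP per gene set (minimum p, 5′-most on
ties) at a 1e-5 threshold, with Benjamini–Hochberg q-values; evidence
across two tests is combined with Fisher's statistic (−2Σln p ~ χ²₄).

### Cross-validation semantics

Families are split into odd/even halves by their stable integer index.
A SNP significant in exactly one half yields an *Ascertained* contrast
(significant half's predicted Δp vs the other half's observed Δp) and a
*Paired* contrast (the complement). For the change test the assignment is
reversed, because there the ascertainment acts on the observed Δp. A SNP
significant in both halves yields two Ascertained contrasts and no Paired
one — the Paired label is reserved for contrasts untouched by the
ascertainment event. This matters because the un-partitioned observed and
predicted Δp share p̂_A, whose estimation error enters both axes with
opposite signs and generates a positive covariance *without any true
prediction*; the validation suite reproduces exactly this artifact
(un-partitioned r ≈ 0.6 on fully neutral data, Paired r ≈ 0).

## Window statistics

Around each focal SNP, 100 bp of flanking sequence per side is taken from
the phased panel, the focal site excluded. S counts biallelic polymorphic
flanking sites; π is mean pairwise difference with the unbiased n/(n−1)
correction (the estimator is not pinned down by convention, so both the
frequency-based and pairwise routes are implemented and tested against
each other); Tajima's D uses the standard a1…e2 constants; Zns is the mean
r² over flanking-site pairs and Z_focal the mean r² of focal-vs-flanking
pairs. Sites with more than two alleles in the sample are excluded
throughout. D is reported missing when S = 0 and Zns when S < 2. The
selected-vs-control contrast is a per-metric one-way ANOVA with missing
values dropped; control windows are a seeded sample of SNPs with test
p > 0.1 (one per gene set).

## The synthetic-data generator

The generator emulates the *structure* of the field experiment, not its
sequences: K distinct haplotypes over biallelic SNPs with uniform panel
frequencies; maternal genotypes drawn Hardy–Weinberg from Q\*(p_cohort);
offspring selfed with probability 0.10, otherwise sired from Q\*(p_M); and
read-pairs drawn as contiguous SNP windows (length centered on 6 SNPs, the
empirical median for paired-end data) from one of the plant's two
haplotypes, with per-base flip probability ε_sim. Coverage is negative
binomial (mean 10 read-pairs per plant × gene set, shape 5) — a
parameterized stand-in for matching the empirical coverage distribution.
Default design: 200 A-families per year with 3 offspring each, plus an
L cohort sized by the survival fraction ((1−α)/α ≈ 86 plants at α = 0.7).
All randomness flows from a single mandatory seed, and outputs are
byte-reproducible.

What it does **not** emulate — and what passing tests therefore cannot
certify about real data: recombinant field haplotypes absent from the
panel, paralogous read mapping, base-quality variation, indels, shared
restriction-site dropout across plants (a flag approximating fixed loci is
the closest knob), population structure in the panel, and a coalescent
history for the haplotypes (they are drawn i.i.d.). The window-statistic
contrasts on simulated panels are therefore null checks, not power
analyses.

## Validation suite and problem sizes

The statistical acceptance checks run at these sizes, chosen to give
stable Monte-Carlo estimates while keeping the suite fast:

* **LRT calibration**: 2000 neutral SNPs (200 families, 3 offspring, K=8,
  ε=0.005); empirical type-I error at 0.05 and a KS test of the statistic
  against χ²(1). Measured type-I ≈ 0.042 — mildly conservative in finite
  samples, inside the acceptance band.
* **Recovery**: 100 replicates of H3 fits at (p_A, p_M, p_L) =
  (0.5, 0.65, 0.4), 300 A-families × 3 offspring plus 300 L plants; MAE
  per frequency ≈ 0.014–0.017, near the binomial information floor.
* **Cross-validation null**: 300 neutral SNPs with a deliberately lenient
  ascertainment threshold (0.2) so that ~100 Paired contrasts exist;
  Paired r within 2 SE of zero, un-partitioned covariance positive.
* **Oracles**: the p_M-linear factorization vs the direct reweighted sire
  sum (1e-10), vectorized family likelihoods vs brute-force genotype
  enumeration (1e-9), window statistics vs a from-scratch implementation
  (1e-9).

## Known limitations

* Maternal inbreeding is not modeled: the maternal prior is Hardy–Weinberg
  within cohort. With ~10% selfing the adult cohort has mild excess
  homozygosity that the prior ignores.
* Hetero-allelic reference lines (residual heterozygosity) are not
  supported; the panel must be haploid/phased upstream.
* Selfed offspring contribute nothing to p_M (they carry no independent
  sire draw); this follows from the transmission model rather than being a
  modeling choice.
* Fecundity-weighted (female) selection, mating-system estimation, and
  recombination within gene sets are out of scope; the mating-system
  classification is consumed as input.
* The likelihood ignores base qualities; reads are bags of SNP calls.
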