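# Methods

## The problem

Tropical beef cattle are hybrids of two subspecies that diverged long ago,
*Bos indicus* and *Bos taurus*. Mutations affecting complex traits arose
independently in the two lineages, so a marker allele can tag a QTL in one
subspecies and nothing in the other ("ghost QTL"). A genomic evaluation
that fits one effect per SNP across a hybrid population averages over
those origins and can both lose prediction accuracy and blur QTL signals.
`boamap` implements the alternative: trace the subspecies of origin of
every chromosome segment with haplotype windows, expand the genotype
matrix by origin, and let a Bayesian mixture regression estimate
origin-specific SNP effects simultaneously.

## Haplotype windows and variant frequencies

The genome is cut into fixed, non-overlapping windows of `window_kb`
kilobases (50, 100 and 250 kb are the standard sizes; 100 kb is the
default used throughout the experiments). The grid is anchored at bp 1 of
each chromosome: a SNP at 1-based position p falls in within-chromosome
window `floor((p-1)/(1000*window_kb))`; bounds are reported 0-based
half-open. Windows containing no SNP are dropped; trailing partial windows
are kept, as are single-SNP windows. Each chromosome copy of each animal
carries one haplotype variant per window — the ordered alleles over the
window's SNPs, bit-packed big-endian in map order (up to 2^m variants for
m SNPs). Variant counts are tallied per subspecies over the haplotype
copies of a purebred reference panel (two per animal); frequencies are
counts over 2 x (panel animals of that subspecies).

## Subspecies-of-origin assignment

A target haplotype with reference frequencies pBi and pBt gets

    b = pBi / (pBi + pBt),

the probability it is indicus in origin; it is called Bi when b >= 0.5
(ties to indicus, exactly as the inequality reads) and Bt otherwise.
Variants absent from both panels are resolved by Hamming distances to the
reference haplotype copies, summed per subspecies with copy multiplicity.
Two modes exist because the published recipe is self-contradictory:

* `as_printed` computes Prob(Bi) = sum(Bi)/(sum(Bi)+sum(Bt)) and assigns
  the haplotype to the larger probability — which is the subspecies whose
  copies are on average *farther* from the query;
* `similarity` averages distances per copy and assigns the smaller mean
  distance, reporting complementary normalised similarities.

`as_printed` is the default for fidelity; every recovery experiment in
this package uses `similarity`, which is the behaviour consistent with the
stated aim of the fallback. An optional panel-size normalisation divides
each sum by the number of copies (the two panels can be very unequal).
Hamming ties assign Bi, mirroring the b >= 0.5 convention.

The two haplotype calls combine into a window diplotype class: Bi
(both indicus), Bt (both taurus) or Bx (one of each). Per-animal indicus
percentage is the fraction of haplotype copies called Bi, optionally
weighted by SNPs per window.

## Origin-partitioned design matrix

For SNP j the origin matrix has columns (3j, 3j+1, 3j+2) for Bi/Bt/Bx.
Every SNP inherits its window's diplotype class, and the animal's whole
0/1/2 dosage lands in that single column; the other two stay structurally
zero. Heterozygous-origin (Bx) windows therefore put the full dosage in
the Bx column rather than splitting alleles between Bi and Bt — this is
what lets the Bx effect capture an indicus x taurus interaction at the
locus, and it preserves the identity that collapsing the three columns of
each SNP reproduces the control (plain dosage) matrix exactly, including
for dosage-1 genotypes inside homozygous-origin windows. No MAF filtering
is applied to columns: the mixture prior lets rare columns have no effect.

## BayesR

The trait model is

    y = 1 mu + cg + age·b + X g + e,

with contemporary group as a factor (reference-level coded), age as a
covariate, and each design-column effect g_i drawn from a four-component
normal mixture with variances {0, 0.0001, 0.001, 0.01} x sigma_g^2 and
Dirichlet(1,1,1,1) proportions. Sampling is single-site Gibbs in fixed
column order: fixed effects from normal full conditionals (flat priors);
per column, the class indicator from the effect-integrated (collapsed)
conditional, then the effect from its normal full conditional; Pr from
Dirichlet(alpha + counts); sigma_e^2 from its scaled-inverse-chi-square
conditional (flat df=-2, scale=0 prior by default); sigma_g^2 optionally
from the nonzero effects' conditional. Defaults are 50,000 iterations
with 20,000 burn-in, thinning 10; posterior summaries average the
retained draws, and PIPs are class-occupancy fractions (each column's PIP
vector sums to 1 exactly). GEBV = X ghat. Identical seed, config and data
give bit-identical chains (a single deterministic RNG stream drives the
whole sweep).

Numerical/initialisation choices that matter:

* **Column centring** (`center=True`): subtracting column means inside the
  sampler (sparsely, via a scalar residual offset, so sparse matrices stay
  sparse). Uncentred origin columns of one window share the window-class
  indicator's mean component, which makes all same-class columns of a
  window strongly correlated and splits posterior inclusion across them.
  Uncentred is the default; every experiment here centres.
* **sigma_g^2 handling.** Three modes. `sampled` (default) is the
  conjugate update. `fixed` pins sigma_g^2 = h2_init x var(y). For sparse
  architectures at small panel sizes, the conjugate update is bistable:
  each column that drifts into the smallest nonzero class contributes
  roughly sigma_g^2 to the update's numerator while adding one to its
  degrees of freedom, so a crowd of weakly informative columns deflates
  sigma_g^2; with tiny class variances the likelihood can no longer push
  the mixture weights away from the Dirichlet prior's pull toward
  uniformity, and the chain settles in a diffuse mode where most columns
  show PIP ~ 0.5-0.75. `empirical` avoids this by pinning sigma_g^2 at an
  empirical-Bayes value from a marginal association screen: the median
  squared marginal OLS effect over columns passing a Bonferroni-style
  z^2 > 2 ln(ncol) cut, divided by the top multiplier (0.01), so the
  largest mixture class matches the effect sizes the data actually show;
  with no screen hits it falls back to the `fixed` value. All mapping
  experiments in this package use `empirical`.
* **Sparse warm start** (`pr_init=(0.997, 0.001, 0.001, 0.001)`): start
  the mixture at a sparse configuration and let the chain grow the model
  from the data, the usual warm start for variable-selection samplers.
  The default start is the prior mean (uniform), which matches the
  expectation that a no-signal dataset reports PIP near the prior mean
  inclusion of 0.75.
* All-zero columns are handled gracefully (their class indicator follows
  Pr); the sigma_g^2 update with no nonzero effects draws from its prior
  (df 4, scale anchored at the h2_init value).

## Evaluation

Phenotypes are adjusted by OLS on contemporary group + age (singleton
groups produce zero residuals and a warning). Folds are a uniform random
k-way split (k=5 default; sizes differ by at most one; a 3695-animal
population yields five folds of 739), persisted to file so every analysis
scores identical validation groups. Accuracy is corr(GEBV, adjusted
phenotype)/sqrt(h2) with h2 = 0.20 by default (the trait the method was
developed for); bias is the OLS slope of GEBV on adjusted phenotype (the
reverse, dispersion-style slope is also reported). Origin assignment uses
only the reference panel, never phenotypes, so it is computed once outside
the CV loop without leakage. The QTL report lists SNP x class rows with
PIP_inclusion at or above a threshold (0.20 default), sorted by PIP, plus
a minimal stacked Manhattan panel helper (Control/Bi/Bt/Bx).

## The synthetic study generator

The generator emulates the study system end to end so every stage is
testable without animal data:

* **Divergence**: per-SNP ancestral frequencies Uniform(0.1, 0.9);
  subspecies frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around them
  (Balding-Nichols), F = 0.3 by default — a deliberate simplification of
  coalescent history that parameterises divergence directly by Fst.
* **Haplotype sharing**: 100 founder haplotypes per subspecies (about a
  cattle effective population size) drawn SNP-wise from the pool
  frequencies; every reference or target haplotype is a mosaic of founders
  with exponential copy tracts (300 kb expected), so window variants recur
  between panel and targets and LD decays over a few hundred kb.
* **Hybrids**: three breed profiles emulate the real populations — a
  graded-up breed at 90% indicus and two stabilised composites at 50% and
  37% — with ancestry tracts from a Markov switch process along the
  genome (switch rate = generations/Morgan at 1 cM/Mb; 8/4/4 generations).
  Tract ancestries are then assigned by per-animal quota so each animal's
  genome-wide indicus fraction matches a Normal(profile, 0.03) target:
  stabilised composites really are tight around their breed mean, and
  without the quota a short simulated genome (20 independent tract units)
  would give within-breed fraction spreads an order of magnitude too wide,
  creating a single genome-wide ancestry factor that confounds mapping.
* **Genome**: 2000 SNPs at uniform 5 kb spacing over 10 chromosomes by
  default (20 SNP per 100 kb window) — a desk-scale stand-in for a dense
  bovine array.
* **QTL**: drawn among SNPs segregating (frequency in [0.1, 0.9]) in both
  ancestral pools — a subspecies-specific effect at a SNP fixed within
  that subspecies is invisible to any method. Three effect architectures:
  `normal` (bivariate normal Bi/Bt effects with configurable correlation,
  0 by default — the two lineages diverged long before the mutations),
  `equal` (unit magnitude, random sign per origin), and `ghost` (unit
  effect in exactly one origin — the classic ghost-QTL scenario the
  origin-partitioned model exists for). With correlation 1 a locus is
  fully origin-independent and the Bx class inherits the common effect.
* **Phenotypes**: true breeding values flow through the TRUE origin design
  (dosage x the true class's effect), scaled to variance h2; residuals
  N(0, 1-h2); contemporary groups nested within breed (the real design
  has no mixed-breed groups) with sd 0.5 effects; an age covariate at
  0.002 units/day over 550-650 days; trait mean 2.5 on the 0-5 scale.
  Realised heritability var(TBV)/var(TBV+e) hits h2 up to sampling error.
* All randomness flows from one seed through named sub-streams (pools,
  panel, hybrids, effects, phenotypes), so components are independently
  reproducible.

What the generator does *not* emulate: genotyping error, imputation
error, pedigree and family structure beyond the admixture profiles,
selection, variable recombination rate, and real site-frequency spectra.
Passing tests show the method's statistical machinery works under
controlled admixture; they do not certify performance on real arrays.

## Experiment designs (problem sizes used)

* **Ancestry recovery**: defaults (Fst 0.3, 100 reference animals per
  subspecies, 300 targets, 100 kb windows). Measured: ~98% window-level
  accuracy with breed means within ~2 points of 90/50/37.
* **QTL recovery**: 1002 animals, 2000 SNP, 10 ghost QTL, h2 = 0.5
  (a deliberately informative trait), 10k/4k Gibbs, five seeds. A QTL
  counts as recovered when a column with PIP > 0.5 lies within one window
  of it (at 5 kb spacing a proxy just across an arbitrary window boundary
  is correct mapping at data resolution); windows not adjacent to any QTL
  window are the null set.
* **Prediction comparison**: 1002 animals, 600 SNP, 12 QTL, h2 = 0.5,
  5-fold CV with shared fold plans, 2000/600 chains, ten replicates for
  the uncorrelated-effects comparison (paired sign test).
* A known limitation measured by the test suite: when effects are fully
  origin-independent, the origin-partitioned matrix costs accuracy at
  this scale (the same effect must be represented in three columns, and
  the class-matched kernel masks cross-class relationship terms) — a
  ridge fit shows the same gap, so it is a property of the representation,
  not the sampler. On dense real-scale data the cost is expected to
  shrink, but at 600-SNP scale the two models are not equivalent.

## Known limitations

* Local ancestry is called per window with no smoothing across windows
  (no HMM); isolated miscalls at tract boundaries are expected.
* The Hamming fallback's printed form assigns to the more distant
  subspecies; both behaviours ship, and analyses must choose.
* Only two-way ancestry; no three-way crosses.
* The sampler is single-threaded by design: reproducibility over speed.
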