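# Methods

`dayflower` implements a complete population-genetic analysis for many small,
partially selfing plant populations sampled across urban and rural habitat
classes, together with a forward-time simulator that generates data with the
same statistical structure so every stage can be exercised and calibrated
without any external dataset.

## Genotype model and filtering

Genotypes are diploid and biallelic; a call is the unordered pair of allele
indices {0, 1} or missing (both gene copies absent together — half-called VCF
genotypes are demoted to missing and logged). All statistics are invariant to
allele relabelling, so no nucleotide information is retained.

Filters reproduce the genotype-matrix-level behaviour of a reduced-
representation SNP-calling workflow:

| filter | default | keep rule |
|---|---|---|
| sample missingness | 0.40 | remove iff missing fraction **>** threshold |
| locus coverage (r) | 0.80 | keep iff called fraction **≥** threshold |
| single SNP per locus group | on | keep first SNP per group tag |
| minor allele frequency | 0.01 | keep iff global maf **≥** threshold |
| observed heterozygosity | 0.95 | keep iff global H_obs **≤** threshold |

maf and H_obs are pooled over all individuals (global filtering), not
per population. Sample exclusion runs once, before the locus filters, on
pre-filter missingness; the locus filters run in the fixed order
coverage → single-SNP → maf → het and the report logs removals per stage.
Because locus removal can change a borderline sample's missing fraction, the
composed pipeline is idempotent stage-wise but not as a whole; we treat the
sample filter as defined on the raw matrix, which is the standard workflow.

## Diversity statistics

Per population and locus, over called genotypes only (no imputation):

* **H_O** — heterozygous calls / called genotypes.
* **H_E** — gene diversity. Default is the small-sample unbiased estimator
  (2n/(2n−1))(1 − Σp̂²), the probability that two gene copies drawn without
  replacement differ; the plain 1 − Σp̂² is available by flag. The unbiased
  form matches the behaviour class of the standard R implementations.
* **A_R** — rarefied allelic richness, Σ_i [1 − C(N−N_i, g)/C(N, g)], the
  exact expected number of distinct alleles among g gene copies drawn without
  replacement. Default g = 5 **gene copies**: a rarefaction target of "5
  alleles" is ambiguous between 5 copies and 5 diploids (10 copies); we adopt
  the gene-copy convention of the hierfstat-style implementations and expose
  g as a parameter. Loci where any population has fewer than g copies are
  skipped for all populations (and logged) so values stay comparable.
* **N_A** — mean observed alleles per locus (1 or 2 for SNPs).
* **F_IS** — 1 − H_O/H_E per locus; the population value aggregates as
  1 − ΣH_O/ΣH_E (ratio of sums) rather than a mean of ratios, which is
  unstable at near-zero-H_E loci. Under partial selfing at rate s, F_IS
  equilibrates at s/(2−s), which the simulator recovers (below).

**Hardy–Weinberg testing** uses the exact conditional test for biallelic
genotypes: given the sample allele counts, P(n_het) ∝ multinomial × 2^n_het.
We report the one-sided heterozygote-deficit p (the direction relevant for
selfers) and a two-sided p (total probability of configurations no more
probable than observed); the per-population deviating-locus fraction uses
the two-sided p at α = 0.05. The original workflow's permutation-based HWE
test is replaced by this deterministic exact equivalent, which is standard
for biallelic data. Monomorphic loci get p = 1 and are flagged, not counted
as testable.

## Differentiation and ordination

* **Nei's standard distance (1972)** D = −ln I, I = J_AB/√(J_A·J_B), with
  J means taken over loci defined in both populations (pairwise-complete
  deletion, logged). The 1972 form (not the 1978 bias-corrected variant) is
  the default because it is the common default of the spreadsheet tools used
  for this analysis class; disjoint fixation gives I = 0 and D = +inf, which
  is propagated as a sentinel — infinite pairs are dropped (greedily, fewest
  labels) before Mantel/PCoA rather than truncated to an arbitrary cap.
* **F_ST** defaults to the G_ST-style estimator (ΣH_T − ΣH_S)/ΣH_T as a
  ratio of locus sums; Weir–Cockerham θ is available for sensitivity
  analysis (`method="wc"`). With no variation at any shared locus F_ST is
  undefined and reported as 0 with a warning.
* **PCoA** is classical Gower double-centering, B = −½·C·D²·C, with an
  `eigh` decomposition. Axes with eigenvalues above a relative tolerance of
  1e−10 are retained; percent variance is relative to the positive-eigenvalue
  mass and the negative mass is reported (semimetric inputs like Bray–Curtis
  legitimately produce negative eigenvalues). Lingoes and Cailliez
  corrections are available but not applied by default.

## Spatial and landscape distances

Geographic distances are haversine great-circle distances on the mean Earth
radius 6371.0088 km; over a metropolitan extent (< 70 km) the deviation from
a geodesic is below 0.5%, immaterial for rank-based Mantel inference.

Landscape dissimilarity is the Bray–Curtis distance Σ|x−y|/Σ(x+y) of
land-cover area vectors around each site. The default uses the 500 m buffer
and the classes {developed, agricultural, forest}; grassland is excluded by
default (the landscape-difference analysis is defined on the three classes
that drive the urban–rural contrast) but can be included by flag, and all
three radii (250/500/1000 m) remain computable for scale selection.

## Resampling inference

All permutation/resampling routines take an explicit integer seed and
canonicalise label order internally, so results are reproducible and
invariant to input ordering.

* **Mantel test**: Pearson r over upper-triangle entries; null by jointly
  permuting rows+columns of one matrix; one-sided "greater"
  p = (hits+1)/(n_perm+1) by default (999 permutations, the vegan
  convention for "up to 1000 permutations"); two-sided by flag.
* **Partial Mantel**: first-order partial correlation r_xy·z from the three
  entry correlations, permuting x, matching the residual-correlation method
  of the standard R implementation.
* **Cross-habitat correlation CI**: plain Mantel tests cannot address the
  pairs that straddle two habitat groups, so the observed statistic is the
  Pearson correlation of the two distances over exactly the between-group
  pairs. The null permutes population labels within the union of the two
  groups (sizes preserved) and recomputes r on the induced between-group
  pairs; the 95% CI is the 2.5/97.5 percentile band of that null, and
  "significant" means the observed r falls outside it. This null reading
  (rather than a bootstrap CI of the observed r) is adopted because it
  matches the way such CIs straddle zero while particular r values are still
  called significant; the bootstrap variant is available by flag.
* **Habitat-pair resampling**: eleven pair categories (4 within-habitat,
  3 rural–urban, 3 urban–urban, ALL); per replicate one pair is drawn
  uniformly from each category and its distance recorded; 1000 replicates
  give the category mean and percentile 95% CI, compared across categories
  by CI overlap. Percentile (not BCa) intervals are used — the procedure is
  a plain resampling summary, not a bias-corrected estimator.

## GLMs and landscape-scale selection

A Gaussian GLM with identity link is ordinary least squares; habitat
comparisons use treatment coding with RA (rural agricultural) as the
reference, so coefficients are urban-vs-rural contrasts. AIC is
−2·logLik + 2·(k+1) with the full Gaussian log-likelihood (constants
included) and k counting intercept plus slopes; the +1 is the variance
parameter, making values identical to R's `AIC(lm(...))`. For each
diversity metric the null (intercept-only) model competes against one model
per buffer radius with developed/agricultural/forest areas (z-scored for
conditioning; selection is invariant to this) as predictors; lowest AIC
wins, exact ties resolving toward fewer predictors. Separately, the
pipeline picks a "best" landscape radius for the differentiation analyses
by maximal all-pairs Mantel r — two distinct scale choices, both reported.

## The simulator

Forward-time Wright–Fisher with partial selfing, implemented as a hybrid:
migration acts deterministically on allele frequencies (the outcross gamete
pool), reproduction is individual-based. Each offspring is selfed with
probability s (two independent gametes from one random resident parent) or
outcrossed (two independent gametes from the post-migration pool); sampling
N offspring provides binomial drift. Migration follows
m_ij = m0·exp(−d_ij/λ_geo)·exp(−BC_ij/λ_env), decaying with geographic
distance and landscape dissimilarity; rows exceeding total rate 1 are
rescaled. Founder events replace a population with N_f individuals drawn
from a source population at a given generation. Initial frequencies are
Beta(0.8, 0.8) (a U-shaped spectrum whose common variants survive a 1%
maf filter); loci are unlinked, matching a one-SNP-per-locus analysis.

The study-scale scenario (`habitat_divergence`) uses 24 populations
(8 RA / 5 UA / 5 UP / 6 UR) in a ~66 km bounding box with UA sites
contracted toward the centre, 600 loci, N = 200, s = 0.9, 50 generations,
3–7 sampled diploids per site and 25% missingness — the sampling regime the
analysis pipeline must tolerate. `founder_parks` adds recent (10
generations) founder events of 5 individuals into each UP/UR site from its
nearest RA/UA source. `ibd` places 8 populations on a 5 km-spaced line with
distance-decaying migration (m0 = 0.2, λ_geo = 4 km, N = 100, 100
generations, 15 samples/site, no missingness) — deliberately a clean,
well-sampled power scenario; `island` is its uniform-migration control and
`null` is near-panmixia. Land-cover compositions are Dirichlet draws
(concentration 50) around habitat-specific mean compositions, converted to
areas by the buffer area πr².

What the generator does *not* emulate: mutation, linkage, selection, seed
banks, polyploidy, spatially continuous habitat, and non-random sampling
within sites. Passing tests therefore demonstrate that the statistics and
inference procedures behave correctly under the stated model — not that the
biological conclusions drawn from any real dataset are robust to
model violations.

## Numerical choices and degenerate inputs

* Rarefaction and Hardy–Weinberg probabilities use log-gamma arithmetic;
  both are verified against exact enumeration (N ≤ 12 copies, n ≤ 8
  diploids) to 1e−12.
* Correlations raise on zero variance rather than returning NaN; partial
  correlations raise when a covariate is collinear (|r| = 1).
* Population statistics skip undefined (population, locus) cells; a
  population with no called genotypes at any locus yields NaN rows, which
  the GLM stage drops with a warning.
* Distance matrices validate symmetry and zero diagonals on construction.

## Problem sizes used in verification

Calibration and recovery checks run at sizes chosen to give stable rates at
desk scale: 200 replicates × 199 permutations for type-I calibration
(Mantel and cross-group), 20 replicates for IBD power, 10 seeds for the
F_IS and founder recoveries, 50 replicates for AIC scale-selection
recovery. The F_IS check recovers s/(2−s) = 0.818 within ±0.08 at
N = 200, 500 loci, 50 generations.
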