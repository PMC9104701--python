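# Methods

`agingomics` re-implements, as a tested pipeline over a synthetic cohort
generator, the bespoke computations of a cross-sectional multi-omic aging
study in Diversity Outbred (DO) mice: sample-mixup QC, TMT peptide-to-protein
quantification, per-gene age-effect models, protein-complex stoichiometry
decay, and kinship-aware age-interactive QTL mapping. This note records the
models, the generator's design, the numerical choices, and the known limits
of what the synthetic experiments demonstrate.

## The synthetic cohort generator

The generator is first-class code, not a fixture: its defaults are the study
design it emulates, and every downstream stage is validated against its
planted ground truth.

**Cohort.** 185 mice in three age groups (33F/29M at 6 mo, 31F/31M at 12 mo,
27F/34M at 18 mo), five breeding generations, 19 proteomics batches of up to
10 mice assigned in randomized order. Age enters every model in years
(0.5, 1.0, 1.5), so slopes are per year of life.

**Genomes.** Two haplotypes per chromosome per mouse, each an 8-state Markov
chain over the founder strains: uniform start, switch to a uniformly chosen
different founder with probability 0.05 per adjacent-marker interval.
Recombination is a per-interval switch probability rather than a genetic-map
model — only the mosaic/LD structure matters for exercising the methods. The
default genome is deliberately small (10 chromosomes × 40 markers, 100 Mb
each); consequences for genome-wide thresholds are discussed under
*Limitations*. Founder probabilities are the one-hot diplotype averaged over
haplotypes (entries in {0, 0.5, 1}), optionally blurred and renormalized.

**Transcripts.** Counts are Gamma–Poisson (negative binomial) with per-gene
dispersion α ∈ [0.05, 0.3] and log2 mean linear in age, sex, generation
(small zero-centered offsets; the study reports generation counts but no
effect sizes) and any planted genotype-by-age interaction; per-sample size
factors are log-normal (sd 0.25).

**Proteins and peptides.** A latent log2 protein signal carries the age/sex
effects plus a complex-structured component built from an age-group-specific
one-factor model: member signal = √r·F + √(1−r)·ε with r(age) = base_r +
Δr·(age − 0.5). This gives exact control of the within-complex pairwise
correlation at each age, which is the quantity the stoichiometry stage
estimates. Peptide intensities are 2^(signal + peptide offset + batch shift +
sample loading + noise); peptides flagged as founder-polymorphic are zeroed
in any mouse whose true diplotype at the gene's nearest marker carries a
non-reference founder (quantification is relative to the reference strain,
so non-reference alleles go undetected), and further values are removed
missing-completely-at-random — MS missingness is not otherwise characterized
by the study. An optional parameter ρ couples the protein residual to the
gene's within-age-group standardized transcript level, for experiments on
transcript–protein concordance; ρ defaults to 0 so that the complex-decay
conditions stay exactly as constructed.

**Planted defects.** Sample swaps exchange the labels of disjoint pairs in
the expression-derived data only. Expression-based haplotype reconstruction
error is modeled as a convex blend q = (1−ε)p + ε·Dirichlet(1) with ε = 0.05:
ε is directly the expected misassigned probability mass. The study does not
state this noise level; it is exposed as a parameter.

**Randomness.** Every operation draws from its own named RNG stream derived
from the master seed, so adding or reordering operations never perturbs the
others, and every output is a pure function of (config, seed).

## Sample-mixup detection

For each mouse, the mean over markers of the Euclidean distance between the
two 8-founder probability rows,

    dbar_i = (1/M) Σ_m ( Σ_a (p_mia − q_mia)² )^{1/2},

is ~0 for matching reconstructions and near √2 for disjoint one-hot rows.
Mice with dbar > 0.8 (strict inequality) are flagged; maps are aligned
beforehand by nearest-marker interpolation (ties to the lower coordinate),
which keeps rows exactly on the simplex. Flagged mice are automatically
cross-matched — each flagged expression profile is compared against every
array profile — and mutual nearest pairs are labeled swap candidates. This
automates a step that is usually done by manual inspection of the flagged
mice; non-mutual flags are marked for exclusion instead.

At the default genome scale the dbar of *unrelated* pairs is ≈ N(0.90,
0.045), because a 400-marker genome has only ~50 independent haplotype
blocks per pair of mice; about 1.5% of random swap pairs therefore fall
below the 0.8 cutoff. At the real study's ~69k markers the distribution
concentrates and the cutoff separates cleanly. The sensitivity tests use the
suite's standard seed and the margin is comfortable there, but "always
detected" is a large-genome property, not a desk-scale one.

## Peptide-to-protein quantification

Protein abundance is `Protein_ij = log2(Σ_{k∈K_j} Peptide_ik / s_i + 1)`
with `s_i = (Σ_L Peptide_il) / max_{q∈batch(i)} (Σ_L Peptide_ql)` computed
from the full observed peptide set before any filtering (loading
normalization precedes peptide selection, and s is not recomputed after the
polymorphic filter). Missing peptides contribute 0 to the sum; a protein is
missing only when all of its peptides are. Proteins missing in strictly more
than half the mice are dropped.

Candidate polymorphic peptides (variant mask marks ≥1 non-reference founder)
are scored by regressing log2(intensity+1) on the 8 founder dosages at the
gene's nearest marker (sex and age as covariates) and correlating the
estimated allele effects with the reference-sharing indicator; r ≥ 0.7
(inclusive) drops the peptide. The study refined this set with data from a
related inbred panel, which is not modeled here.

Batch structure is removed per protein by REML (statsmodels `MixedLM`):
abundance ~ age group (categorical) + sex with a random batch intercept; the
batch BLUP is subtracted, fixed effects stay in place. Note that a uniform
rescaling of one batch's intensities is *not* absorbed by s (which is
within-batch relative); it surfaces as a batch shift of log2 c and is
removed here — the batch model, not the scaling, owns between-batch level
differences. For genetic mapping, features are transformed to rank-normal
scores Φ⁻¹((rank − 0.5)/n), average ranks for ties, missing preserved.

## Age-effect models

Transcripts passing the detection filter (≥1 read in ≥ half the samples) are
modeled by a negative-binomial GLM with log link: log μ = offset(log s) +
sex + generation + β_age·age_years. The per-gene dispersion is profiled out
by MLE under the full model and held fixed for the null fit, so the
likelihood-ratio statistic compares nested models at a common dispersion and
is non-negative; p-values come from χ². No empirical-Bayes dispersion
shrinkage is applied — at n = 185 it is second-order. Size factors are
median-of-ratios with a geometric-mean reference, and downstream uses
(rank-normalization, correlation) are monotone-transform-tolerant, so a
full variance-stabilizing transform is not reimplemented; normalized
expression is log2(count/s + 1). Note that a large same-sign perturbed
fraction would leak into median-of-ratios size factors; at realistic DE
fractions (a few percent) the leakage is negligible.

Proteins are modeled by OLS on sex + generation + age_years with a marginal
F-test for the tested term given all others (the study's ANOVA is not
specified as type I or II; this is the type-II-like choice). Effects are
reported as log2 fold change per year with SE, standardized effect
(slope/SE), and Benjamini–Hochberg q-values (the study's "FDR"); the
discovery threshold is FDR < 0.01. The age-by-sex test adds age×sex to the
additive model.

## Complex stoichiometry decay

Within each catalog complex with ≥4 observed members, Pearson correlations
are computed for every member pair within each age group over
pairwise-complete samples (pairs with <10 complete samples in any group are
excluded; the study states no minimum — 10 keeps single-group correlation
noise below ~0.3 SD). Per-pair OLS slopes of r on age (years) give Δr/year.
The complex-level estimate is a mixed model

    r_ijk = μ + u[ij] + (β_age + v[ij])·x_k + ε_ijk,

with independent random intercept u and slope v (no covariance is stated by
the study), fitted by REML; boundary or non-converging fits fall back to the
mean of per-pair slopes with its empirical SE. The age covariate is in years
even though the joint model is sometimes written in months — the reported
slopes are per year, and the unit choice only rescales β.

Significance is by permutation of the sample-to-age assignment (default
B = 1000): pair-level empirical p-values pool the permuted |slope| null
across pairs of the same complex (pooling sharpens resolution beyond 1/B)
with the add-one estimator over the pooled count, then BH across all pairs
(threshold FDR < 0.1); complex-level p-values use the complex's own permuted
distribution (threshold P < 0.05). Because every pair is observed at all
three ages, the mixed model's fixed slope equals the mean of per-pair
slopes, and the permutation replicates use that closed form rather than
refitting REML B times; the equality is asserted by a test.

## QTL mapping

Kinship is the realized genomic relationship from founder probabilities,
K[j,k] = (1/M) Σ_m Σ_a p_mja·p_mka, computed leave-one-chromosome-out for
scanning and over all loci for the permutation null. The null mixed model
y = covariates + u + ε, u ~ N(0, τ²K), is profiled over h = τ²/(τ²+σ²) on an
eigendecomposition of K (grid plus golden-section refinement; ties resolve
to the smallest h, so K = I returns h = 0). ML rather than REML is used so
nested likelihood ratios — and hence LODs — are well defined. The variance
ratio is estimated once per (phenotype, chromosome) under the no-QTL model
and held fixed across loci, which makes each marker fit a GLS in a whitened
basis and guarantees LOD = (n/2)·log10(RSS_null/RSS_marker) ≥ 0. The eight
founder-dosage columns are rank-deficient with the intercept; least squares
via `lstsq`/pseudoinverse handles this, and LOD is invariant to the choice.
A brute-force GLS scan with the explicit covariance matrix serves as the
independent oracle; the fast path matches it to 1e-6 on small instances.

Age-interactive scans add dosage×age columns and test them against the
additive model at the same marker (LOD_int). Genome-wide thresholds use
residual permutation: fit y = sex + age + u with the all-loci kinship, keep
fitted fixed effects plus the kinship BLUP in place, permute the residuals,
rescan, and take the 95th percentile of the genome-wide maxima. In batch
mode one pooled threshold is derived by spreading the permutation replicates
across phenotypes, matching the study's single study-wide threshold;
per-phenotype thresholds are also available.

Peaks are the per-chromosome maximum above the significant or suggestive
(LOD_int > 6.0) level; local means same chromosome within 10 Mb of the gene
(the study never defines local/distal numerically). Hotspots are 4-Mb
half-open windows stepped by 1 Mb containing strictly more than 30 distal
peaks, merged when overlapping; membership is refined in a single pass by
dropping members whose |mean correlation| with the others is < 0.3
(inclusive retention at 0.3).

## Power

The two-group power uses the noncentral t (df = 2n−2, noncentrality
d·√(n/2)); at n = 64/group, d = 0.5 SD, α = 0.05 it gives 0.8015, matching
the printed 0.80. The normal approximation is available and agrees to two
decimals (and is used automatically where the noncentral t overflows).

QTL power is a simulation at the generator's default genome: a bi-allelic
QTL (founders split 4/4) explaining 20% of phenotypic variance is planted at
a random marker; the genome-wide threshold comes from 200 permutation-style
null scans at GWER 0.05; power is the fraction of 200 replicates whose
maximum additive LOD exceeds it. **At this reduced genome the measured power
is ≈ 0.96, not the study's 0.80.** The discrepancy is a multiplicity effect,
not an estimation error: 400 markers support a genome-wide threshold of
≈ 6.1, while the full-genome burden behind the printed figure implies ≈ 7.7;
with expected LOD (n/2)·log10(1/0.8) ≈ 9.0 at the QTL, the exceedance
probability is ~0.96 at the former and ~0.89 at the latter (measured
diagnostically). Reproducing 0.80 would require the full ~64k-locus genome,
which is outside this package's desk scale by design.

## Problem sizes and runtime

Default experiment sizes are chosen so the whole validation suite runs on a
single CPU: 185 mice, 400 markers, 300 genes, ~1550 peptides; 200–1000
permutations for stoichiometry and QTL thresholds; calibration experiments
use 200–500 null features or 300 null complexes. These sizes put
Monte-Carlo standard errors comfortably inside each check's tolerance.

## Limitations

- The genome is a miniature: no X-chromosome dosage, no genetic-map
  expansion across DO generations, no real marker content; genome-wide
  thresholds and mixup-distance concentration are both scale-dependent (see
  above).
- One peptide maps to one protein; no shared-peptide inference, no isotope
  impurity correction.
- Missing peptides are MCAR; real MS missingness is intensity-dependent.
- The dispersion model has no trend over mean expression; calibration at
  n = 185 does not rely on one.
- Passing calibration and recovery on this generator shows the estimators
  are correct under their assumed models, not that those models capture all
  structure of real aging cohorts (e.g., cell-composition shifts).
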