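# Methods

This note records the models behind `batchfst`, the parameter choices that
matter, what the synthetic generator does and does not emulate, and the
numerical conventions adopted where the design was genuinely open.

## The batch-effect problem

A genotype cohort assembled from several sequencing centers confounds
biology with technology: if one center's pipeline produces more spurious
heterozygote calls than another's, every statistic that accumulates rare
alleles — LoF burdens, singleton counts, derived-allele and introgression
tallies — acquires a center-dependent offset, and between-center allele
frequency contrasts acquire excess variance. `batchfst` quantifies this
fingerprint three ways: per-individual count models, per-SNV scaled Fst
against a permutation null, and the sampling-design association between
populations and centers.

## Rare-event counters

All counters operate on biallelic SNVs that are polymorphic across the
whole dataset (multi-allelic records, non-SNVs and monomorphic records are
dropped at read time, with counts logged). Conventions:

* **LoF**: three-way deleterious consensus of the functional predictors
  *and* no homozygous-alt genotype anywhere in the cohort. The
  homozygosity screen is cohort-wide, not per-population: a single
  homozygote anywhere indicates a dispensable gene rather than a severe
  loss of function. Counted as het genotypes per sample (hom-alt is
  impossible by construction). Variants without predictor labels are never
  LoF and never benign.
* **Singletons**: AC = 1 over the whole cohort; the count is assigned to
  the unique het carrier, so the per-sample counts sum exactly to the
  number of singleton variants (a conservation law asserted in the tests).
* **Derived singletons**: among singletons, sites with the degenerate
  ancestral codes '.' (no alignment), '-' (lineage-specific insertion) or
  'N' (allele not present) are excluded; the singleton is derived iff
  AA = REF, i.e. the single ALT copy is the new allele. An AA matching
  neither REF nor ALT is excluded and logged — such a site cannot be
  oriented, and silently keeping it either way would bias the derived
  fraction. AA comparison is case-insensitive by default (ancestral-state
  pipelines emit lowercase for low-confidence calls); a strict-case option
  exists in the Sprime reader where the same question arises.
* **Introgressed alleles**: an (SNV, population) entry contributes the
  sample's copy number of the introgressed allele (0/1/2), only to samples
  of that population. REF can be the introgressed allele, in which case
  copies are 2 − dosage.
* Missing genotypes ('./.') contribute 0 to every count and to AC.

## Weir–Cockerham Fst between centers

For one population and one SNV, K centers with n diploid individuals each
(the equal-n design below), the single-locus Weir & Cockerham (1984)
estimator θ̂ = a/(a+b+c) is computed from the among-center (a),
among-individual-within-center (b) and within-individual (c) variance
components, using per-center ALT frequencies and observed heterozygote
proportions. Sites monomorphic in the subsample are undefined and
excluded. The implementation is vectorised over SNVs; the test suite pins
it to an independent brute-force oracle (a literal three-level nested
ANOVA on expanded allele copies) to 10⁻¹⁰ on 1,000 random tables.

**Equal-n subsampling.** To remove the sampling imbalance between centers,
exactly n = 5 individuals are drawn per center without replacement
(seeded); centers with fewer than n individuals in the population are
excluded, and a population needs at least two eligible centers. n = 5
matches the smallest per-center sample encountered in the motivating
multi-center design and is configurable.

**MAF_P.** The pooled frequency over the subsampled centers is
P_ap = Σ_c a_c / (K·2n) with a_c the ALT *copy count* at center c; 2n is
the number of allele copies each center contributes. The copy-count
reading is adopted because it bounds P_ap in [0, 1]. MAF_P = min(P_ap,
1 − P_ap).

**MAF-conditional maximum and scaling.** θ̂ is bounded by a function of
MAF, so raw values at different frequencies are not comparable. For
m = round(K·2n·MAF_P) minor copies, the maximally differentiated
configuration packs the copies into centers sequentially, fixing whole
centers for the minor allele before starting the next. Within the one
partially filled center the copies are spread over as many heterozygotes
as possible (m′ ≤ n copies become m′ hets; m′ > n becomes m′ − n
hom-minor plus 2n − m′ hets). Exhaustive enumeration over *all* genotype
configurations at K ∈ {2, 3}, n ∈ {2, 3, 4} confirms this arrangement
attains the maximum at every achievable copy number, whereas packing the
partial center with homozygotes does not: homozygotes inflate the
among-individual component b and can drive θ̂ of the partial-fill
configuration to zero (e.g. K = 2, n = 2, m = 2: one hom-minor gives
θ̂ = 0, two hets give 0.5). The scaled value is
max(θ̂, 0)/θ̂_max, clamped to [0, 1]; negative raw estimates are floored at
zero so the scaled values remain comparable. For a few degenerate designs
(a single minor copy at very small K·n) θ̂_max itself is ≤ 0; those sites
have no defined scaled value and are dropped, like monomorphic ones. The
packed configuration always scores exactly 1 against its own maximum — a
self-normalisation identity asserted in the tests.

**MAF summaries.** Mean scaled Fst is reported per distinct MAF value and
per half-open 0.05-wide bin ([0, 0.05), …, last bin closed at 0.5; label =
left edge). The Spearman correlation (mid-rank ties; a constant mean
vector is reported as rho = 0) between distinct MAF values and their mean
scaled Fst summarises the frequency dependence. Both groupings are
emitted; the distinct-MAF grouping is the default for the null contrast
below, the bins exist for plotting.

## Monte Carlo permutation null

Under no center-specific artifacts, the center labels of the subsampled
individuals are exchangeable. The null profile reassigns the labels at
random within the already-subsampled equal-n pool — the same design under
which the observed Fst was computed, so per-site allele counts, MAFs and
maxima are invariant and only θ̂ is recomputed — and averages scaled Fst
within MAF category; the final null value per category is the mean over
permutations (default 100, configurable; per-permutation values are
retained for dispersion). The departure is the slope of an OLS fit of
observed category means on null means, intercept retained (the intercept
is reported, not interpreted); the slope's two-sided p-value comes from
the standard regression t-test. Calibration and power are exercised in the
acceptance tests: with equal error rates in all centers the slope falls in
[0.9, 1.1] in ≥ 18/20 replicates; with one center at e_c = 0.01 and the
rest clean it exceeds 1 with p < 0.01 in ≥ 18/20, and rho < 0.

A magnitude caveat: with the generator's *independent* per-sample error
flips, most error-created alleles are subsample singletons, and a single
allele copy is always concentrated in exactly one center — such sites are
permutation-invariant and contribute no slope signal. The detectable
excess comes from the minority of sites where two or more error copies
co-occur in the error-prone center, so the injected slopes here sit a few
percent above 1. Real center artifacts are systematic (the same spurious
call recurs across samples of a center), which concentrates many copies
per center and can push slopes several-fold above 1; the generator makes
the conservative choice and the calibration/power contrast, not the slope
magnitude, is the meaningful output at this scale.

## Association models

**Mixed model.** log(S) ~ center + (1 | continent/population): fixed
center effect, nested random intercepts, fitted by maximum likelihood
(REML likelihoods are not comparable across fixed-effect structures) with
statsmodels' linear mixed models; the LRT against the center-free null
uses χ² with #centers − 1 degrees of freedom (the random-effect structure
is identical between the models, so no boundary correction arises). Only
centers present in every population enter the contrast; the reference
center is the alphabetically first. Natural log; samples with S = 0 are
excluded by default, with a log(S + 1) alternative (`zero_policy`). A
constant response short-circuits to zero coefficients and zero variance
components. Wald z p-values are reported per coefficient. The test suite
cross-checks the fixed effects against lme4 (via Rscript) to 5 × 10⁻³.

**Correspondence analysis.** χ² of independence (no continuity
correction) plus the SVD of the standardized-residual matrix
D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}; principal coordinates are singular vectors
scaled by singular values over the square-root masses, inertia per
dimension is the squared singular value, and Σ inertia = χ²/N exactly.
Zero-margin rows/columns are dropped with a warning.

**Wilcoxon contrasts.** Two-sided rank-sum tests for every unordered
center pair within a population, upper-triangular output, no
multiple-testing correction. Exact enumeration when both groups have ≤ 20
samples and the pooled values are tie-free; the normal approximation with
tie correction otherwise.

## Synthetic cohort generator

The generator's defaults define the study conditions: 4 populations in 2
continents, 4 centers, 50 samples per population, 20,000 variants.

* **SFS**: global allele counts i ∈ 1..2N−1 with weight 1/i^α (α = 1),
  the neutral expectation — every downstream statistic is MAF-conditioned,
  so an SFS rich in rare variants is the only distributional requirement.
* **Population structure**: per-population frequencies are Balding–Nichols
  Beta perturbations of the global frequency with F = 0.01, a mild
  divergence that keeps the nested random effects of the mixed model
  non-degenerate without simulating demography.
* **Center assignment**: per-population probability vectors over centers,
  by default a skewed base vector rotated across populations so every
  population over-represents a different center — the uneven sampling that
  makes center confounding possible in real projects.
* **Error model**: hom-ref → het flips with per-center probability e_c,
  applied after the Hardy–Weinberg draw; spurious rare heterozygotes are
  the center-attributable failure mode of interest, and one-directional
  flips keep the truth bookkeeping simple. Realistic magnitudes are in the
  0.1–1% per-site range; the rates are free parameters, not asserted
  cohort values. AC is recomputed after injection and
  monomorphic-after-error variants are removed.
* **Annotation structure**: AA = REF with probability 0.8, ALT with 0.1,
  and the remaining 0.1 split over '.', '-', 'N' (configurable weights);
  a configurable fraction (0.3) of variants is coding; error-created
  coding variants draw a three-way deleterious consensus with probability
  0.9 (predictor concordance on artifacts — errors look deleterious to all
  predictors at once), clean coding variants with baseline 0.05, other
  label patterns from independent 0.3 Bernoullis with accidental three-way
  consensus broken, so the consensus channel is identifiable.
* **Counts for model validation**: `simulate_count_table` draws log-normal
  per-individual counts (baseline 3,000, continent/population/individual
  log-sd 0.15/0.10/0.10, rounded to integers) with an additive per-center
  log effect — the magnitudes of real per-individual singleton tallies,
  where rounding noise is negligible.

What the generator does **not** emulate: linkage disequilibrium,
recombination, demographic history, read-level error processes, and —
deliberately — *correlated* center errors (the same artifact recurring
across samples). Passing tests therefore demonstrate the statistical
machinery (calibration, power direction, exact counting, determinism) on
an idealised cohort, not the magnitude of any real cohort's batch effect.

## Problem sizes and numerical conventions

The acceptance checks run at 200 samples × 20,000 SNVs × 100 permutations
× 20 replicates for the Fst null, 500 samples × 100 replicates for the
mixed model, and a 5,000-SNV four-population cohort for the end-to-end
determinism check — sizes at which every targeted property is stable on a
single CPU. Other conventions: genotype codes {0, 1, 2, −1 missing};
coordinates 1-based as in VCF; all RNG via numpy Generators seeded from
explicit integers; pipeline stage seeds are derived deterministically from
the base seed and recorded in the manifest; TSV/JSON outputs are written
with stable ordering so identical configs yield byte-identical artifacts.

## Known limitations

* The slope magnitude under injected errors is small (see the caveat
  above); detecting weak, correlated real-world artifacts may need more
  permutations or larger subsamples than the defaults.
* The equal-n design discards information from large centers (by design,
  to remove sampling imbalance); n > 5 is worth using when every center
  is deep.
* The mixed model assumes log-normal counts; strongly skewed or
  zero-inflated responses would call for a count-likelihood model, which
  is out of scope.
* Predictor-label mapping to deleterious/benign is a declared convention
  (SIFT "D", PolyPhen-2 "D", MutationAssessor "H"); real annotation
  pipelines differ in category granularity and the mapping is
  configurable rather than asserted.
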