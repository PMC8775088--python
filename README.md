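# batchfst

Detection and quantification of **sequencing-center batch effects** in
multi-center genotype cohorts.

Large sequencing projects distribute their samples over several sequencing
centers, each with its own library preparation, machines and pipelines.
Center-specific genotyping error preferentially creates *spurious rare
variants* — ghost heterozygotes that inflate every statistic built on rare
alleles: per-individual loss-of-function (LoF) burdens, singleton and
derived-singleton counts, and tallies of archaic introgressed alleles.
`batchfst` is for population and medical geneticists who need to ask, before
trusting such statistics: *does the sequencing center leave a detectable
fingerprint in my cohort?*

## What it computes

**Rare-event counters.** Per individual: LoF variants (deleterious by all
three functional predictors — SIFT, PolyPhen-2, MutationAssessor — and with
no homozygous-alt carrier in the cohort), benign-consensus variants,
singletons (cohort ALT count AC = 1), derived singletons (singletons whose
ancestral-allele flag AA equals REF; AA ∈ {'.', '-', 'N'} excluded), and
copies of population-specific introgressed alleles from an Sprime-style
table.

**MAF-scaled between-center Fst.** Within one population, *n* = 5
individuals are drawn per center and Weir & Cockerham's (1984) single-locus
θ̂ = a/(a+b+c) is estimated among centers for every SNV. Because the
attainable θ̂ depends on the minor allele frequency, each estimate is scaled
by the maximum θ̂ achievable at the site's MAF_P, where

```
P_ap = Σ_c a_c / (K · 2n),   MAF_P = min(P_ap, 1 − P_ap)
```

with `a_c` the ALT copies at center c among K centers of n diploid
individuals. The maximum is realised by the "packed" configuration that
concentrates the minor-allele copies center by center; the scaled values
lie in [0, 1] and are comparable across frequencies.

**Monte Carlo permutation null.** Center labels are repeatedly reshuffled
within the equal-n pool, scaled Fst is recomputed per SNV and averaged
within MAF category, and the batch effect is quantified as the slope of an
OLS fit of the observed category means on the null means: slope ≈ 1 means
no center fingerprint; slope > 1 means excess differentiation tied to the
real center assignment. A Spearman correlation between MAF and the mean
scaled Fst summarises the frequency profile.

**Association models.** A hierarchical mixed model
`log(S) ~ center + (1 | continent/population)` (ML fits, likelihood-ratio
test against the center-free null), correspondence analysis with χ² of the
population × center sampling design, and pairwise Wilcoxon rank-sum
contrasts between centers within a population.

**Synthetic cohorts.** A seeded generator produces every input the
pipeline needs: Hardy–Weinberg genotypes at frequencies from a 1/i-type
site-frequency spectrum, uneven center assignment, center-specific
hom-ref→het error injection with full truth bookkeeping, predictor-label
and ancestral-allele annotation, and Sprime-style introgression tables.

## Worked example

```python
import batchfst as bf

spec = bf.CohortSpec(
    n_variants=20_000, n_populations=1, n_continents=1, samples_per_pop=200,
    center_error_rates={"BGI": 0.01}, seed=7,
)
cohort = bf.generate_cohort(spec)

counts = bf.build_count_table(cohort.genotypes, cohort.metadata)
print(counts.groupby("center")["n_singletons"].mean())

res = bf.fit_center_mixed_model(counts, "n_singletons")
print(res.coefficients, f"LRT p = {res.lrt_p:.3g}")

scan = bf.ScaledFstScan(n_per_center=5, n_permutations=100, random_state=1)
scan.fit_from_cohort(cohort.genotypes, cohort.metadata, "POP1")
print(f"slope = {scan.slope_:.3f}, rho = {scan.rho_:.3f}")
```

With a 1% per-site error rate injected into the BGI center this prints
(mean singletons per individual) BCM 3.3, **BGI 22.9**, BI 3.2, WUGSC 3.8;
the mixed model recovers the fingerprint as a BGI coefficient of 2.01 on
the log scale (z = 22.5, LRT p = 8 × 10⁻⁶⁴) while the clean centers stay
at zero; and the scaled-Fst scan reports slope = 1.015 against the
permutation null (p = 2.8 × 10⁻³²) with rho = −0.480 — observed
between-center differentiation sits above the null and concentrates at low
MAF, the signature of center-specific error. Re-running with
`center_error_rates={}` pulls the slope back to ≈ 1 and equalises the
center means.

The same analysis runs from the shell:

```sh
batchfst all --config run.yaml        # simulate → count → ca → models → fst → null → report
batchfst report --out runs/demo       # re-render the report of a finished run
```

Every run writes a `manifest.json` with seeds and SHA-256 digests of all
artifacts; identical configs reproduce byte-identical TSV/JSON outputs.

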