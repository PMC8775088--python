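"""Seeded generator of multi-center genotype cohorts.

The generator emulates the structure of a multi-population sequencing
cohort in which each individual's genotypes were produced by one of
several sequencing centers: within-population Hardy–Weinberg genotypes at
frequencies drawn from a neutral-like site-frequency spectrum rich in
singletons, non-uniform assignment of individuals to centers, and a
center-specific genotype-error process that converts hom-ref calls into
spurious heterozygotes (the error mode that inflates rare-variant counts).
Sequencing errors in real pipelines affect roughly 0.1–1% of sequenced
nucleotides, which motivates the magnitude of the per-center error-rate
dial; the generator does not assert cohort-specific values.

No linkage disequilibrium, recombination or demographic history is
simulated: every downstream statistic here is per-site and MAF-conditioned,
so an SFS with abundant rare variants is the only distributional feature
that matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ABSENT, BASES, BENIGN, DELETERIOUS, GenotypeMatrix

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_sprime_table",
    "simulate_count_table",
]

DEFAULT_CENTERS = ("BCM", "BGI", "BI", "WUGSC")


@dataclass
class CohortSpec:
    """Parameters of a synthetic multi-center cohort.

    ``center_assignment_weights`` is a (n_populations, n_centers) matrix of
    probabilities (rows sum to 1); the default rotates a skewed base vector
    across populations so that every population over-represents a different
    center, emulating the uneven sampling of real multi-center projects.
    ``center_error_rates`` maps center label to the per-site probability
    e_c of flipping a hom-ref genotype into a spurious het.
    ``aa_missing_rates`` gives the relative weights of the degenerate
    ancestral-allele codes '.', '-' and 'N', which share the probability
    mass left after assigning AA=REF (0.8) and AA=ALT (0.1).
    """

    n_populations: int = 4
    n_continents: int = 2
    centers: tuple[str, ...] = DEFAULT_CENTERS
    samples_per_pop: int = 50
    center_assignment_weights: np.ndarray | None = None
    n_variants: int = 20_000
    sfs_exponent: float = 1.0
    center_error_rates: dict[str, float] = field(default_factory=dict)
    frac_coding: float = 0.3
    predictor_concordance: float = 0.9
    baseline_concordance: float = 0.05
    predictor_marginal: float = 0.3
    aa_missing_rates: dict[str, float] = field(
        default_factory=lambda: {".": 0.05, "-": 0.025, "N": 0.025}
    )
    pop_divergence: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_variants <= 0 or self.samples_per_pop <= 0:
            raise ValueError("n_variants and samples_per_pop must be positive")
        if self.n_populations < 1 or self.n_continents < 1:
            raise ValueError("need at least one population and continent")
        if self.n_continents > self.n_populations:
            raise ValueError("more continents than populations")
        if len(self.centers) < 2:
            raise ValueError("need at least two centers")
        if self.center_assignment_weights is None:
            base = np.linspace(2.0, 1.0, len(self.centers))
            w = np.stack([np.roll(base, i) for i in range(self.n_populations)])
            self.center_assignment_weights = w / w.sum(axis=1, keepdims=True)
        self.center_assignment_weights = np.asarray(
            self.center_assignment_weights, dtype=float
        )
        if self.center_assignment_weights.shape != (
            self.n_populations,
            len(self.centers),
        ):
            raise ValueError("center_assignment_weights must be (n_pops, n_centers)")
        if (self.center_assignment_weights < 0).any() or not np.allclose(
            self.center_assignment_weights.sum(axis=1), 1.0
        ):
            raise ValueError("center_assignment_weights rows must sum to 1")
        rates = {c: float(self.center_error_rates.get(c, 0.0)) for c in self.centers}
        if any(not 0 <= e <= 1 for e in rates.values()):
            raise ValueError("center error rates must lie in [0, 1]")
        self.center_error_rates = rates
        for name, p in [
            ("sfs_exponent", None),
            ("frac_coding", self.frac_coding),
            ("predictor_concordance", self.predictor_concordance),
            ("baseline_concordance", self.baseline_concordance),
            ("predictor_marginal", self.predictor_marginal),
            ("pop_divergence", self.pop_divergence),
        ]:
            if p is not None and not 0 <= p <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(w < 0 for w in self.aa_missing_rates.values()):
            raise ValueError("aa_missing_rates must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.n_populations * self.samples_per_pop

    def population_labels(self) -> list[str]:
        return [f"POP{i + 1}" for i in range(self.n_populations)]

    def continent_of(self, pop_index: int) -> str:
        return f"CONT{pop_index % self.n_continents + 1}"


@dataclass
class CohortTruth:
    """Bookkeeping of the injected error process (final variant indexing)."""

    error_variant_idx: np.ndarray
    error_sample_idx: np.ndarray
    error_created_variants: np.ndarray
    per_center_errors: dict[str, int]
    center_error_rates: dict[str, float]
    n_monomorphic_removed: int
    n_eligible_homref: dict[str, int]


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    truth: CohortTruth


def _sample_sfs_frequencies(rng, n_variants, n_copies, exponent):
    i = np.arange(1, n_copies)
    w = 1.0 / i.astype(float) ** exponent
    counts = rng.choice(i, size=n_variants, p=w / w.sum())
    return counts / n_copies


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a cohort from a :class:`CohortSpec`; reproducible from its seed.

    Genotypes are drawn per population from Hardy–Weinberg proportions at
    frequencies sampled from the 1/i^exponent SFS (with a small
    Balding–Nichols perturbation of per-population frequencies when
    ``pop_divergence`` > 0).  Center-specific errors then flip hom-ref
    genotypes to het with probability e_c; AC is recomputed over the whole
    cohort after injection and variants monomorphic after the error process
    are removed, so every emitted variant is biallelic and polymorphic
    across the dataset.
    """
    rng = np.random.default_rng(spec.seed)
    pops = spec.population_labels()

    sample_ids, pop_col, cont_col, center_col = [], [], [], []
    for pi, pop in enumerate(pops):
        for j in range(spec.samples_per_pop):
            sample_ids.append(f"S{pi:02d}{j:04d}")
            pop_col.append(pop)
            cont_col.append(spec.continent_of(pi))
        center_col.extend(
            rng.choice(
                spec.centers,
                size=spec.samples_per_pop,
                p=spec.center_assignment_weights[pi],
            )
        )
    metadata = pd.DataFrame(
        {"pop": pop_col, "super_pop": cont_col, "center": center_col},
        index=pd.Index(sample_ids, name="sample"),
    )
    present = set(metadata["center"])
    empty = [c for c in spec.centers if c not in present]
    if empty:
        raise ValueError(
            f"centers {empty} received zero samples; increase samples_per_pop "
            "or adjust center_assignment_weights"
        )

    N = spec.n_samples
    p_global = _sample_sfs_frequencies(rng, spec.n_variants, 2 * N, spec.sfs_exponent)

    # Per-population frequencies: Balding–Nichols Beta around the global p.
    F = spec.pop_divergence
    pop_freqs = np.empty((spec.n_populations, spec.n_variants))
    if F > 0:
        shape = (1.0 - F) / F
        for pi in range(spec.n_populations):
            pop_freqs[pi] = rng.beta(p_global * shape, (1.0 - p_global) * shape)
    else:
        pop_freqs[:] = p_global

    genotypes = np.empty((spec.n_variants, N), dtype=np.int8)
    pop_index = {p: i for i, p in enumerate(pops)}
    sample_pop = np.array([pop_index[p] for p in pop_col])
    for pi in range(spec.n_populations):
        cols = np.nonzero(sample_pop == pi)[0]
        genotypes[:, cols] = rng.binomial(
            2, pop_freqs[pi][:, None], size=(spec.n_variants, cols.size)
        ).astype(np.int8)

    # Center-specific error process: hom-ref -> spurious het.
    e_per_sample = np.array([spec.center_error_rates[c] for c in center_col])
    flips = (genotypes == 0) & (
        rng.random((spec.n_variants, N)) < e_per_sample[None, :]
    )
    n_eligible = {}
    per_center = {}
    for c in spec.centers:
        cols = np.array(center_col) == c
        n_eligible[c] = int((genotypes[:, cols] == 0).sum())
        per_center[c] = int(flips[:, cols].sum())
    genotypes[flips] = 1
    err_v, err_s = np.nonzero(flips)

    ac = genotypes.astype(np.int64).sum(axis=1)
    keep = (ac > 0) & (ac < 2 * N)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            "every simulated variant is monomorphic after the error process; "
            "check sfs_exponent / n_variants"
        )
    old_to_new = np.full(spec.n_variants, -1)
    old_to_new[keep] = np.arange(keep.sum())
    flip_kept = keep[err_v]
    truth_v = old_to_new[err_v[flip_kept]]
    truth_s = err_s[flip_kept]
    error_created = np.unique(truth_v)

    genotypes = genotypes[keep]
    ac = ac[keep]
    nv = genotypes.shape[0]

    ref_i = rng.integers(0, 4, size=nv)
    alt_i = (ref_i + rng.integers(1, 4, size=nv)) % 4
    ref = np.array(BASES)[ref_i]
    alt = np.array(BASES)[alt_i]

    deg_codes = list(spec.aa_missing_rates)
    deg_w = np.array([spec.aa_missing_rates[c] for c in deg_codes], dtype=float)
    deg_mass = 0.1
    if deg_w.sum() > 0:
        deg_p = deg_w / deg_w.sum() * deg_mass
    else:
        deg_p = np.zeros_like(deg_w)
    probs = np.concatenate(([0.8, 0.1 + (deg_mass - deg_p.sum())], deg_p))
    aa_choice = rng.choice(len(probs), size=nv, p=probs)
    aa = np.empty(nv, dtype=object)
    aa[aa_choice == 0] = ref[aa_choice == 0]
    aa[aa_choice == 1] = alt[aa_choice == 1]
    for k, code in enumerate(deg_codes):
        aa[aa_choice == 2 + k] = code

    coding = rng.random(nv) < spec.frac_coding
    is_err = np.zeros(nv, dtype=bool)
    is_err[error_created] = True
    q = np.where(is_err, spec.predictor_concordance, spec.baseline_concordance)
    all_del = coding & (rng.random(nv) < q)
    p1 = np.full(nv, ABSENT, dtype=object)
    p2 = np.full(nv, ABSENT, dtype=object)
    p3 = np.full(nv, ABSENT, dtype=object)
    rest = coding & ~all_del
    for arr in (p1, p2, p3):
        arr[rest] = np.where(
            rng.random(int(rest.sum())) < spec.predictor_marginal, DELETERIOUS, BENIGN
        )
    # independent draws may still concord; break the tie so only the
    # concordance channel produces three-way deleterious consensus
    acc = rest & (p1 == DELETERIOUS) & (p2 == DELETERIOUS) & (p3 == DELETERIOUS)
    p3[acc] = BENIGN
    for arr in (p1, p2, p3):
        arr[all_del] = DELETERIOUS

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": (np.arange(nv) + 1) * 100,
            "ref": ref,
            "alt": alt,
            "ac": ac,
            "aa": aa,
            "p1": p1,
            "p2": p2,
            "p3": p3,
            "coding": coding,
        }
    )
    gm = GenotypeMatrix(samples=sample_ids, variants=variants, genotypes=genotypes)
    truth = CohortTruth(
        error_variant_idx=truth_v,
        error_sample_idx=truth_s,
        error_created_variants=error_created,
        per_center_errors=per_center,
        center_error_rates=dict(spec.center_error_rates),
        n_monomorphic_removed=n_removed,
        n_eligible_homref=n_eligible,
    )
    return SyntheticCohort(genotypes=gm, metadata=metadata, truth=truth)


def generate_sprime_table(
    cohort: SyntheticCohort, frac_introgressed: float, seed: int = 0
) -> pd.DataFrame:
    """Mark a random fraction of variants as introgressed, per population.

    Emulates the per-population output format of archaic-introgression
    callers: rows of (CHROM, POS, ALLELE, POP) where ALLELE (REF or ALT of
    the matched variant) is the putatively introgressed allele.
    """
    if not 0.0 <= frac_introgressed <= 1.0:
        raise ValueError("frac_introgressed must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    v = cohort.genotypes.variants
    nv = len(v)
    rows = []
    for pop in sorted(cohort.metadata["pop"].unique()):
        k = int(round(frac_introgressed * nv))
        idx = np.sort(rng.choice(nv, size=k, replace=False))
        use_alt = rng.random(k) < 0.5
        for i, ua in zip(idx, use_alt):
            allele = v["alt"].iat[i] if ua else v["ref"].iat[i]
            rows.append((v["chrom"].iat[i], int(v["pos"].iat[i]), allele, pop))
    return pd.DataFrame(rows, columns=["CHROM", "POS", "ALLELE", "POP"])


def simulate_count_table(
    n_continents: int = 2,
    pops_per_continent: int = 5,
    samples_per_pop: int = 50,
    centers: tuple[str, ...] = DEFAULT_CENTERS,
    center_log_effects: dict[str, float] | None = None,
    baseline: float = 3000.0,
    sd_continent: float = 0.15,
    sd_pop: float = 0.1,
    sd_individual: float = 0.1,
    response: str = "n_singletons",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-individual rare-event counts with a known center effect.

    Counts are log-normal on the latent scale — continent and
    population-within-continent random intercepts plus an additive
    per-center log effect and individual noise — rounded to integers
    (baseline 3000 puts them in the range of real per-individual singleton
    tallies, where rounding noise is negligible).  Used to validate the
    mixed-model contrast: the true multiplicative center effect is
    ``exp(center_log_effects[c])``.
    """
    rng = np.random.default_rng(seed)
    center_log_effects = center_log_effects or {}
    rows = []
    mu = np.log(baseline)
    for ci in range(n_continents):
        u_cont = rng.normal(0.0, sd_continent)
        for pj in range(pops_per_continent):
            u_pop = rng.normal(0.0, sd_pop)
            pop = f"POP{ci + 1}{pj + 1}"
            for k in range(samples_per_pop):
                center = centers[rng.integers(len(centers))]
                beta = center_log_effects.get(center, 0.0)
                eps = rng.normal(0.0, sd_individual)
                s = max(1, int(round(np.exp(mu + u_cont + u_pop + beta + eps))))
                rows.append(
                    (f"T{ci}{pj}{k:04d}", pop, f"CONT{ci + 1}", center, s)
                )
    return pd.DataFrame(
        rows, columns=["sample", "pop", "super_pop", "center", response]
    ).set_index("sample")
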