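"""Per-individual counts of rare genomic events.

Five counters, all sensitive to center-specific genotyping error because
they accumulate over rare alleles:

* **LoF**: coding variants called deleterious by all three functional
  predictors, restricted to variants with no homozygous-alt carrier
  anywhere in the cohort (a homozygote would point to a dispensable gene
  rather than a true loss of function); counted as the number of het
  genotypes per sample.
* **benign**: coding variants called benign by all three predictors,
  counted as ALT allele copies carried.
* **singletons**: variants whose ALT allele appears exactly once in the
  whole cohort (AC = 1); the single carrier scores 1.
* **derived singletons**: singletons whose single ALT copy is the derived
  allele, i.e. the ancestral-allele flag AA equals REF; sites with the
  degenerate AA codes '.', '-' or 'N' (no alignment, lineage-specific
  insertion, allele not present) are excluded.
* **introgressed alleles**: copies of the population-specific introgressed
  allele (from an Sprime-style table) carried by the sample.

Missing genotypes contribute 0 to every count and to AC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import AA_DEGENERATE, BENIGN, DELETERIOUS, MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "classify_lof",
    "classify_benign",
    "count_lof_per_sample",
    "count_benign_per_sample",
    "count_singletons",
    "count_derived_singletons",
    "count_introgressed",
    "build_count_table",
]


def _all_label(v: pd.DataFrame, label: str) -> np.ndarray:
    return (
        v["coding"].to_numpy()
        & (v["p1"] == label).to_numpy()
        & (v["p2"] == label).to_numpy()
        & (v["p3"] == label).to_numpy()
    )


def classify_lof(gm: GenotypeMatrix) -> np.ndarray:
    """Indices of LoF variants: three-way deleterious consensus, no hom-alt.

    Variants with absent predictor labels are never LoF.  The homozygosity
    exclusion is cohort-wide: a single hom-alt genotype anywhere removes
    the variant.
    """
    consensus = _all_label(gm.variants, DELETERIOUS)
    has_homalt = (gm.genotypes == 2).any(axis=1)
    return np.nonzero(consensus & ~has_homalt)[0]


def classify_benign(gm: GenotypeMatrix) -> np.ndarray:
    """Indices of coding variants with three-way benign consensus."""
    return np.nonzero(_all_label(gm.variants, BENIGN))[0]


def count_lof_per_sample(gm: GenotypeMatrix, lof_idx: np.ndarray) -> np.ndarray:
    """Number of LoF variants at which each sample is heterozygous."""
    return (gm.genotypes[lof_idx] == 1).sum(axis=0).astype(np.int64)


def count_benign_per_sample(gm: GenotypeMatrix, benign_idx: np.ndarray) -> np.ndarray:
    """ALT copies carried per sample over the benign-consensus variants."""
    g = gm.genotypes[benign_idx]
    return np.where(g == MISSING, 0, g).sum(axis=0).astype(np.int64)


def count_singletons(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample count of cohort singletons (AC = 1) carried.

    The sum over samples equals the number of singleton variants exactly.
    """
    singleton = gm.variants["ac"].to_numpy() == 1
    return (gm.genotypes[singleton] == 1).sum(axis=0).astype(np.int64)


def count_derived_singletons(gm: GenotypeMatrix) -> np.ndarray:
    """Per-sample count of singletons whose ALT copy is the derived allele.

    AA is compared case-insensitively.  Singletons with a degenerate AA
    code are excluded; an AA matching neither REF nor ALT is also excluded
    (and logged) — the convention here, since upstream annotation offers
    no way to orient such a site.
    """
    v = gm.variants
    singleton = v["ac"].to_numpy() == 1
    aa = v["aa"].astype(str).str.upper().to_numpy()
    ref = v["ref"].astype(str).str.upper().to_numpy()
    alt = v["alt"].astype(str).str.upper().to_numpy()
    degenerate = np.isin(aa, [c.upper() for c in AA_DEGENERATE])
    derived = singleton & ~degenerate & (aa == ref)
    unresolved = singleton & ~degenerate & (aa != ref) & (aa != alt)
    if unresolved.any():
        logger.info(
            "%d singletons with AA matching neither REF nor ALT excluded",
            int(unresolved.sum()),
        )
    return (gm.genotypes[derived] == 1).sum(axis=0).astype(np.int64)


def count_introgressed(
    gm: GenotypeMatrix,
    sprime_map: dict[tuple[str, int, str], str],
    metadata: pd.DataFrame,
) -> np.ndarray:
    """Copies of the population's introgressed allele carried per sample.

    An entry (chrom, pos, pop) -> allele contributes only to samples of
    that population: ALT-introgressed sites contribute the dosage code,
    REF-introgressed sites contribute 2 - dosage (missing genotypes 0).
    """
    v = gm.variants
    pos_index = {
        (str(c), int(p)): i
        for i, (c, p) in enumerate(zip(v["chrom"].astype(str), v["pos"]))
    }
    counts = np.zeros(gm.n_samples, dtype=np.int64)
    sample_pop = np.array(
        [metadata["pop"].get(s, None) for s in gm.samples], dtype=object
    )
    by_pop: dict[str, tuple[list[int], list[bool]]] = {}
    for (chrom, pos, pop), allele in sprime_map.items():
        i = pos_index.get((chrom, pos))
        if i is None:
            continue
        is_alt = allele.upper() == str(v["alt"].iat[i]).upper()
        by_pop.setdefault(pop, ([], []))[0].append(i)
        by_pop[pop][1].append(is_alt)
    for pop, (idx, is_alt) in by_pop.items():
        cols = np.nonzero(sample_pop == pop)[0]
        if cols.size == 0:
            continue
        g = gm.genotypes[np.asarray(idx)][:, cols]
        dosage = np.where(g == MISSING, 0, g)
        alt_mask = np.asarray(is_alt)[:, None]
        copies = np.where(
            alt_mask, dosage, np.where(g == MISSING, 0, 2 - dosage)
        )
        counts[cols] += copies.sum(axis=0)
    return counts


def build_count_table(
    gm: GenotypeMatrix,
    metadata: pd.DataFrame,
    sprime_map: dict | None = None,
) -> pd.DataFrame:
    """Assemble the per-individual count table with sample metadata.

    Columns: pop, super_pop, center, n_lof, n_benign, n_singletons,
    n_derived_singletons, n_introgressed — indexed by sample, restricted to
    samples present in both the genotype matrix and the metadata.
    """
    lof_idx = classify_lof(gm)
    benign_idx = classify_benign(gm)
    table = pd.DataFrame(
        {
            "n_lof": count_lof_per_sample(gm, lof_idx),
            "n_benign": count_benign_per_sample(gm, benign_idx),
            "n_singletons": count_singletons(gm),
            "n_derived_singletons": count_derived_singletons(gm),
            "n_introgressed": (
                count_introgressed(gm, sprime_map, metadata)
                if sprime_map
                else np.zeros(gm.n_samples, dtype=np.int64)
            ),
        },
        index=pd.Index(gm.samples, name="sample"),
    )
    keep = [s for s in gm.samples if s in metadata.index]
    out = metadata.loc[keep, ["pop", "super_pop", "center"]].join(table.loc[keep])
    return out
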