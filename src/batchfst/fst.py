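"""Weir–Cockerham Fst between sequencing centers, with MAF-aware scaling.

The batch-effect statistic works per SNV: individuals of one population are
grouped by the sequencing center that produced their genotypes, the same
number ``n`` of individuals is drawn from every center to remove sampling
imbalance, and Weir & Cockerham's (1984) single-locus theta is estimated
among centers.  Because the magnitude of theta is bounded by the site's
minor allele frequency, each estimate is divided by the maximum theta
attainable at that MAF (the "packed" configuration, in which whole centers
are fixed for the minor allele); the scaled values are comparable across
frequencies and can be averaged within MAF categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CenterAlleleTable",
    "FstRecord",
    "weir_cockerham_fst",
    "weir_cockerham_theta",
    "compute_maf_p",
    "packed_configuration",
    "max_fst_given_maf",
    "scale_fst",
    "subsample_centers",
    "fst_scan",
    "summarize_by_maf",
    "assign_maf_bins",
]

MISSING = -1


@dataclass(frozen=True)
class CenterAlleleTable:
    """Genotype composition of one biallelic SNV across K centers.

    ``counts`` has shape (K, 3): per center the number of hom-ref, het and
    hom-alt individuals.  All centers carry the same number ``n`` of diploid
    individuals (the equal-n subsampling design).
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("counts must have shape (K, 3)")
        if c.shape[0] < 2:
            raise ValueError("need at least two centers (K >= 2)")
        if (c < 0).any():
            raise ValueError("genotype counts must be non-negative")
        if len(set(c.sum(axis=1).tolist())) != 1:
            raise ValueError("all centers must hold the same number of individuals")
        object.__setattr__(self, "counts", c)

    @property
    def K(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts[0].sum())

    @property
    def alt_copies(self) -> np.ndarray:
        """ALT allele copies a_c per center (n_het + 2 * n_hom_alt)."""
        return self.counts[:, 1] + 2 * self.counts[:, 2]


def compute_maf_p(table: CenterAlleleTable) -> tuple[float, float]:
    """Pooled ALT frequency over the subsampled centers and its MAF.

    ``p_ap = sum_c a_c / (K * 2n)`` where ``a_c`` counts ALT copies at center
    c and ``2n`` is the number of allele copies each center contributes;
    ``maf_p = min(p_ap, 1 - p_ap)``.
    """
    copies = 2 * table.n
    p_ap = float(table.alt_copies.sum()) / (table.K * copies)
    return p_ap, min(p_ap, 1.0 - p_ap)


def _theta_components(n_i, p_i, h_i):
    """Weir & Cockerham (1984) variance components a, b, c (vectorised).

    ``n_i``, ``p_i``, ``h_i`` have shape (K, ...): per-center sample sizes
    (diploid individuals), ALT allele frequencies and observed heterozygote
    proportions.  Returns arrays broadcast over the trailing dimensions.
    """
    n_i = np.asarray(n_i, dtype=float)
    p_i = np.asarray(p_i, dtype=float)
    h_i = np.asarray(h_i, dtype=float)
    r = n_i.shape[0]
    nsum = n_i.sum(axis=0)
    nbar = nsum / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    return a, b, c, pbar


def weir_cockerham_fst(table: CenterAlleleTable) -> float:
    """Single-locus Weir & Cockerham (1984) theta-hat among centers.

    Returns NaN (the undefined marker) for sites monomorphic in the
    subsample or when the variance components sum to zero.
    """
    counts = table.counts
    n_i = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_i)
        h_i = counts[:, 1] / n_i
    a, b, c, pbar = _theta_components(n_i, p_i, h_i)
    if pbar <= 0.0 or pbar >= 1.0:
        return float("nan")
    denom = a + b + c
    if denom == 0.0 or not np.isfinite(denom):
        return float("nan")
    return float(a / denom)


def weir_cockerham_theta(genotypes: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised theta-hat for many SNVs at once.

    Parameters
    ----------
    genotypes : int array, shape (n_samples, n_variants)
        Diploid ALT-dosage codes {0, 1, 2}; -1 marks a missing genotype.
    labels : int array, shape (n_samples,)
        Center index per sample (0..K-1).

    Returns
    -------
    theta : float array, shape (n_variants,)
        NaN where the site is monomorphic in the sample or undefined.
    """
    genotypes = np.asarray(genotypes)
    labels = np.asarray(labels)
    centers = np.unique(labels)
    K = centers.size
    if K < 2:
        raise ValueError("need at least two centers")
    nv = genotypes.shape[1]
    n_i = np.empty((K, nv))
    p_i = np.empty((K, nv))
    h_i = np.empty((K, nv))
    for k, c in enumerate(centers):
        g = genotypes[labels == c]
        valid = g != MISSING
        n = valid.sum(axis=0)
        alt = np.where(valid, g, 0).sum(axis=0)
        het = (g == 1).sum(axis=0)
        n_i[k] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = alt / (2 * n)
            h_i[k] = het / n
    a, b, c_, pbar = _theta_components(n_i, p_i, h_i)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c_)
    theta = np.where((pbar > 0) & (pbar < 1), theta, np.nan)
    return theta


def packed_configuration(m: int, K: int, n: int) -> CenterAlleleTable:
    """The maximally differentiated arrangement of ``m`` minor-allele copies.

    Centers are filled one after another until the copies run out; the
    remaining centers are fixed for the major allele.  Within the partially
    filled center the copies are spread over as many heterozygotes as
    possible (``take`` copies become ``take`` hets when ``take <= n``, else
    ``take - n`` hom-minor plus ``2n - take`` hets): exhaustive enumeration
    over genotype configurations at small K, n shows this arrangement —
    not a hom-minor fill — attains the maximum theta at every achievable
    copy number, because concentrating copies into homozygotes inflates the
    among-individual-within-center variance component.  The minor allele is
    represented as ALT (the labelling does not affect theta).
    """
    if not 0 < m <= K * n:
        raise ValueError("m must satisfy 0 < m <= K*n (minor-allele copies)")
    counts = np.zeros((K, 3), dtype=np.int64)
    remaining = m
    for k in range(K):
        take = min(remaining, 2 * n)
        if take <= n:
            het, hom = take, 0
        else:
            het, hom = 2 * n - take, take - n
        counts[k] = (n - het - hom, het, hom)
        remaining -= take
    return CenterAlleleTable(counts)


@lru_cache(maxsize=None)
def _max_fst_cached(m: int, K: int, n: int) -> float:
    return weir_cockerham_fst(packed_configuration(m, K, n))


def max_fst_given_maf(maf_p: float, K: int, n: int) -> float:
    """Maximum theta-hat attainable at MAF ``maf_p`` with K centers of n diploids.

    The minor-allele copy number is ``m = round(K * 2n * maf_p)``; the packed
    configuration realising the maximum is evaluated with the same estimator
    used for observed sites.  Returns NaN when the MAF corresponds to zero
    copies (monomorphic).
    """
    if not 0.0 <= maf_p <= 0.5:
        raise ValueError("maf_p must lie in [0, 0.5]")
    m = int(round(K * 2 * n * maf_p))
    if m == 0:
        return float("nan")
    return _max_fst_cached(m, K, n)


def scale_fst(fst_raw: float, fst_max: float) -> float:
    """Scaled Fst: negative estimates floored at 0, result clamped to [0, 1]."""
    if not np.isfinite(fst_max) or fst_max <= 0:
        return float("nan")
    return min(max(fst_raw, 0.0) / fst_max, 1.0)


def subsample_centers(
    metadata: pd.DataFrame,
    population: str,
    n: int = 5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Draw exactly ``n`` individuals per eligible center within a population.

    Centers with fewer than ``n`` individuals in the population are excluded;
    at least two eligible centers are required.  Returns the metadata rows of
    the selected samples (a view into the grouping design, with the original
    sample IDs as index).
    """
    rng = np.random.default_rng(rng)
    pop = metadata[metadata["pop"] == population]
    if pop.empty:
        raise ValueError(f"population {population!r} not present in metadata")
    chosen = []
    excluded = []
    for center, grp in sorted(pop.groupby("center"), key=lambda kv: kv[0]):
        if len(grp) < n:
            excluded.append(center)
            continue
        idx = rng.choice(len(grp), size=n, replace=False)
        chosen.append(grp.iloc[np.sort(idx)])
    if len(chosen) < 2:
        raise ValueError(
            f"population {population!r}: fewer than two centers with >= {n} "
            f"individuals (excluded: {excluded})"
        )
    out = pd.concat(chosen)
    out.attrs["excluded_centers"] = excluded
    return out


@dataclass
class FstRecord:
    """Per-SNV between-center differentiation record."""

    variant: int
    fst_raw: float
    maf_p: float
    fst_max: float
    fst_scaled: float
    maf_bin: float


def assign_maf_bins(maf: np.ndarray, bin_width: float = 0.05) -> np.ndarray:
    """Left edge of the half-open MAF bin ([0,w), ..., last bin closed at 0.5)."""
    maf = np.asarray(maf, dtype=float)
    edges = np.floor(maf / bin_width) * bin_width
    top = bin_width * (np.ceil(0.5 / bin_width) - 1)
    return np.minimum(edges, top)


def fst_scan(
    genotypes: np.ndarray,
    labels: np.ndarray,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Per-SNV raw, maximum and scaled Fst for an equal-n center design.

    ``genotypes`` is (n_samples, n_variants) with samples already subsampled
    to ``n`` per center; ``labels`` gives each sample's center.  Sites
    monomorphic in the subsample are dropped.  Returns a DataFrame with
    columns variant, fst_raw, maf_p, fst_max, fst_scaled, maf_bin.
    """
    genotypes = np.asarray(genotypes)
    labels = np.asarray(labels)
    centers, counts = np.unique(labels, return_counts=True)
    if centers.size < 2:
        raise ValueError("need at least two centers")
    if len(set(counts.tolist())) != 1:
        raise ValueError("design must hold the same number of samples per center")
    K, n = centers.size, int(counts[0])

    theta = weir_cockerham_theta(genotypes, labels)
    alt = np.where(genotypes == MISSING, 0, genotypes).sum(axis=0)
    p_ap = alt / (K * 2 * n)
    maf = np.minimum(p_ap, 1.0 - p_ap)
    keep = np.isfinite(theta) & (maf > 0)

    # sites whose MAF-conditional maximum is not positive (possible for a
    # single minor copy at small designs) have no defined scaled value
    m_all = np.rint(K * 2 * n * maf).astype(int)
    max_by_m = {mi: _max_fst_cached(mi, K, n) for mi in np.unique(m_all[keep])}
    keep &= np.array([max_by_m.get(mi, np.nan) > 0 for mi in m_all])

    idx = np.nonzero(keep)[0]
    maf_kept = maf[idx]
    fst_max = np.array([max_by_m[mi] for mi in m_all[idx]])
    scaled = np.clip(np.maximum(theta[idx], 0.0) / fst_max, 0.0, 1.0)
    return pd.DataFrame(
        {
            "variant": idx,
            "fst_raw": theta[idx],
            "maf_p": maf_kept,
            "fst_max": fst_max,
            "fst_scaled": scaled,
            "maf_bin": assign_maf_bins(maf_kept, bin_width),
        }
    )


def summarize_by_maf(records: pd.DataFrame, bin_width: float = 0.05):
    """Mean scaled Fst per distinct MAF and per MAF bin, with Spearman rho.

    rho correlates the distinct MAF values with their mean scaled Fst
    (mid-rank tie convention).  Returns (per_maf, per_bin, rho, rho_p);
    rho is NaN when fewer than two distinct MAF values are present.
    """
    per_maf = (
        records.groupby("maf_p")["fst_scaled"].agg(["mean", "size"]).reset_index()
    )
    per_maf.columns = ["maf_p", "mean_fst_scaled", "n_snvs"]
    bins = assign_maf_bins(records["maf_p"].to_numpy(), bin_width)
    per_bin = (
        records.assign(maf_bin=bins)
        .groupby("maf_bin")["fst_scaled"]
        .agg(["mean", "size"])
        .reset_index()
    )
    per_bin.columns = ["maf_bin", "mean_fst_scaled", "n_snvs"]
    if len(per_maf) < 2:
        return per_maf, per_bin, float("nan"), float("nan")
    means = per_maf["mean_fst_scaled"].to_numpy()
    if np.ptp(means) == 0.0:
        # all means tied: mid-ranks are constant, the rank covariance is 0
        return per_maf, per_bin, 0.0, 1.0
    rho, rho_p = stats.spearmanr(per_maf["maf_p"], means)
    return per_maf, per_bin, float(rho), float(rho_p)
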