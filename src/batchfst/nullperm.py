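"""Monte Carlo permutation null for the scaled-Fst profile.

Under the hypothesis of no center-specific genotyping artifacts, assigning
individuals to centers at random should produce the same between-center
differentiation as the real assignment.  The null profile is built by
repeatedly permuting center labels within the already-subsampled equal-n
pool (the design under which the observed Fst was computed), recomputing
scaled Fst for every SNV and averaging within MAF category.  The departure
from the null is quantified by the slope of an ordinary least-squares fit
of the observed category means on the null category means (intercept
retained); a slope of 1 means the observed profile is exchangeable with
the null, a slope well above 1 means the real center assignment carries
excess differentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from scipy import stats

from .fst import (
    _max_fst_cached,
    assign_maf_bins,
    weir_cockerham_theta,
)

MISSING_CODE = -1

__all__ = [
    "NullSummary",
    "permute_centers",
    "null_profile",
    "observed_vs_null_slope",
]


@dataclass
class NullSummary:
    """Observed vs permutation-null scaled-Fst profile for one population."""

    categories: np.ndarray          # distinct MAF values (or bin left edges)
    observed: np.ndarray            # observed mean scaled Fst per category
    null_mean: np.ndarray           # permutation mean per category
    null_per_permutation: np.ndarray  # (n_permutations, n_categories)
    slope: float
    intercept: float
    slope_p: float
    rho: float
    rho_p: float
    n_permutations: int
    n_variants: int
    seed: int | None
    category_kind: str

    def to_json(self, path: str) -> None:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def permute_centers(
    labels: np.ndarray, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Random reassignment of center labels to the same individuals.

    The label multiset is preserved, so the equal-n design (n per center)
    survives any permutation.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    return labels[rng.permutation(labels.size)]


def _category_means(values: np.ndarray, codes: np.ndarray, n_cat: int) -> np.ndarray:
    finite = np.isfinite(values)
    sums = np.bincount(codes[finite], weights=values[finite], minlength=n_cat)
    cnts = np.bincount(codes[finite], minlength=n_cat)
    with np.errstate(invalid="ignore"):
        return np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)


def observed_vs_null_slope(
    observed: np.ndarray, null_mean: np.ndarray
) -> tuple[float, float, float]:
    """OLS of observed category means on null category means.

    Returns (slope, intercept, two-sided p-value of the slope).  Requires
    at least three shared categories; a null vector without variance makes
    the fit undefined (NaNs returned).
    """
    observed = np.asarray(observed, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    ok = np.isfinite(observed) & np.isfinite(null_mean)
    if ok.sum() < 3:
        raise ValueError("need at least three shared MAF categories")
    x, y = null_mean[ok], observed[ok]
    if np.ptp(x) == 0.0:
        return float("nan"), float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def null_profile(
    genotypes: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 100,
    seed: int | None = None,
    bin_width: float = 0.05,
    category: str = "maf",
) -> NullSummary:
    """Observed and Monte Carlo scaled-Fst profiles for an equal-n design.

    ``genotypes`` is (n_samples, n_variants) for the subsampled individuals
    (n per center); ``labels`` their observed center assignment.
    ``category`` selects the MAF grouping: ``"maf"`` uses the distinct
    MAF values of the subsample, ``"bin"`` the half-open ``bin_width`` bins.
    Sites monomorphic in the subsample are excluded once (the subsampled
    individuals, and hence every site's allele counts and MAF, are
    invariant under label permutation).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if category not in ("maf", "bin"):
        raise ValueError("category must be 'maf' or 'bin'")
    rng = np.random.default_rng(seed)
    genotypes = np.asarray(genotypes)
    labels = np.asarray(labels)
    centers, per = np.unique(labels, return_counts=True)
    if len(set(per.tolist())) != 1:
        raise ValueError("equal-n design required (same count per center)")
    K, n = centers.size, int(per[0])

    alt = np.where(genotypes == MISSING_CODE, 0, genotypes).sum(axis=0)
    p_ap = alt / (K * 2 * n)
    maf = np.minimum(p_ap, 1.0 - p_ap)

    theta_obs = weir_cockerham_theta(genotypes, labels)
    keep = np.isfinite(theta_obs) & (maf > 0)
    m_all = np.rint(K * 2 * n * maf).astype(int)
    max_by_m = {mi: _max_fst_cached(mi, K, n) for mi in np.unique(m_all[keep])}
    keep &= np.array([max_by_m.get(mi, np.nan) > 0 for mi in m_all])
    g = genotypes[:, keep]
    maf = maf[keep]
    fst_max = np.array([max_by_m[mi] for mi in m_all[keep]])

    if category == "maf":
        cats, codes = np.unique(maf, return_inverse=True)
    else:
        bins = assign_maf_bins(maf, bin_width)
        cats, codes = np.unique(bins, return_inverse=True)
    n_cat = cats.size

    def scaled(theta):
        return np.clip(np.maximum(theta, 0.0) / fst_max, 0.0, 1.0)

    obs_scaled = scaled(theta_obs[keep])
    observed = _category_means(obs_scaled, codes, n_cat)

    null = np.empty((n_permutations, n_cat))
    for b in range(n_permutations):
        perm = labels[rng.permutation(labels.size)]
        theta = weir_cockerham_theta(g, perm)
        null[b] = _category_means(scaled(theta), codes, n_cat)
    null_mean = np.nanmean(null, axis=0)

    try:
        slope, intercept, slope_p = observed_vs_null_slope(observed, null_mean)
    except ValueError:
        # fewer than three usable categories: profile still reported,
        # departure slope undefined
        slope = intercept = slope_p = float("nan")
    ok = np.isfinite(observed)
    if ok.sum() >= 2 and np.ptp(observed[ok]) > 0:
        rho, rho_p = stats.spearmanr(cats[ok], observed[ok])
    else:
        rho, rho_p = (0.0, 1.0) if ok.sum() >= 2 else (np.nan, np.nan)
    return NullSummary(
        categories=cats,
        observed=observed,
        null_mean=null_mean,
        null_per_permutation=null,
        slope=slope,
        intercept=intercept,
        slope_p=slope_p,
        rho=float(rho),
        rho_p=float(rho_p),
        n_permutations=n_permutations,
        n_variants=int(keep.sum()),
        seed=seed,
        category_kind=category,
    )
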