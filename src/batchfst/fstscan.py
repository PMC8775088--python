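"""One-stop estimator for the MAF-scaled between-center Fst analysis.

``ScaledFstScan.fit(X, y)`` takes a genotype matrix (samples x variants,
ALT-dosage codes) and each sample's sequencing-center label, draws the
equal-n per-center design, computes per-SNV Weir-Cockerham theta, scales it
by the MAF-conditional maximum, summarises the profile by MAF category, and
contrasts it against a Monte Carlo permutation null.  Intended to be run
per population (the grouping the batch-effect question is posed in).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fst import fst_scan, summarize_by_maf
from .nullperm import NullSummary, null_profile

__all__ = ["ScaledFstScan"]


class ScaledFstScan(BaseEstimator):
    """Between-center scaled-Fst scan with permutation null.

    Parameters
    ----------
    n_per_center : int
        Individuals subsampled per center (centers with fewer are dropped;
        at least two eligible centers are required).
    n_permutations : int
        Monte Carlo permutations of the center labels.
    bin_width : float
        Width of the MAF bins used for the binned summary.
    category : {"maf", "bin"}
        MAF grouping used for the observed/null profiles and the slope.
    random_state : int or None
        Seeds both the subsampling and the permutations.

    Fitted attributes
    -----------------
    records_ : DataFrame with per-SNV fst_raw, maf_p, fst_max, fst_scaled,
        maf_bin; per_maf_, per_bin_ : profile summaries; rho_, rho_p_ :
        Spearman correlation of MAF with mean scaled Fst; null_ :
        :class:`NullSummary`; slope_, intercept_, slope_p_ : observed-vs-
        null linear fit; centers_, subsample_index_ : the design drawn.
    """

    def __init__(
        self,
        n_per_center: int = 5,
        n_permutations: int = 100,
        bin_width: float = 0.05,
        category: str = "maf",
        random_state: int | None = None,
    ):
        self.n_per_center = n_per_center
        self.n_permutations = n_permutations
        self.bin_width = bin_width
        self.category = category
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_variants) matching y")
        rng = np.random.default_rng(self.random_state)

        centers, counts = np.unique(y, return_counts=True)
        eligible = centers[counts >= self.n_per_center]
        self.excluded_centers_ = sorted(
            str(c) for c in centers[counts < self.n_per_center]
        )
        if eligible.size < 2:
            raise ValueError(
                f"fewer than two centers with >= {self.n_per_center} samples"
            )
        rows = []
        for c in eligible:
            idx = np.nonzero(y == c)[0]
            rows.append(np.sort(rng.choice(idx, size=self.n_per_center,
                                           replace=False)))
        sub = np.concatenate(rows)
        self.centers_ = [str(c) for c in eligible]
        self.subsample_index_ = sub
        labels = y[sub]
        G = X[sub]

        self.records_ = fst_scan(G, labels, bin_width=self.bin_width)
        self.per_maf_, self.per_bin_, self.rho_, self.rho_p_ = summarize_by_maf(
            self.records_, bin_width=self.bin_width
        )
        perm_seed = int(rng.integers(2**31 - 1))
        self.null_: NullSummary = null_profile(
            G,
            labels,
            n_permutations=self.n_permutations,
            seed=perm_seed,
            bin_width=self.bin_width,
            category=self.category,
        )
        self.slope_ = self.null_.slope
        self.intercept_ = self.null_.intercept
        self.slope_p_ = self.null_.slope_p
        return self

    def fit_from_cohort(self, gm, metadata: pd.DataFrame, population: str):
        """Fit on one population of a genotype matrix + metadata table."""
        pop_samples = metadata.index[metadata["pop"] == population]
        idx = gm.sample_indexer(pop_samples)
        X = gm.genotypes[:, idx].T
        y = metadata.loc[pop_samples, "center"].to_numpy()
        return self.fit(X, y)
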