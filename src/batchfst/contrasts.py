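"""Pairwise Wilcoxon rank-sum contrasts between centers within a population.

Two-sided rank-sum (Mann-Whitney) tests for every unordered center pair,
reported as an upper-triangular p-value table; no multiple-testing
correction is applied.  Exact enumeration is used when both groups have at
most 20 samples and the pooled values carry no ties, the normal
approximation with tie correction otherwise.  Centers with fewer than two
samples yield undefined (NaN) entries.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pairwise_wilcoxon"]

EXACT_MAX_N = 20


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(len(x), len(y)) <= EXACT_MAX_N) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def pairwise_wilcoxon(
    counts: pd.DataFrame, population: str, response: str
) -> pd.DataFrame:
    """Upper-triangular matrix of pairwise center p-values in one population."""
    sub = counts[counts["pop"] == population]
    if sub.empty:
        raise ValueError(f"population {population!r} not present")
    groups = {c: g[response].to_numpy(dtype=float)
              for c, g in sub.groupby("center")}
    centers = sorted(groups)
    if len(centers) < 2:
        raise ValueError(f"population {population!r} has fewer than two centers")
    out = pd.DataFrame(np.nan, index=centers, columns=centers)
    for a, b in itertools.combinations(centers, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            continue
        out.loc[a, b] = _rank_sum_p(groups[a], groups[b])
    return out
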