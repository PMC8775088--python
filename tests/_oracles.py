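"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the Weir–Cockerham
oracle expands genotype counts into literal per-copy allele indicators and
runs the three-level nested ANOVA (centers / individuals / gene copies)
from first principles; the chi-square oracle is the Pearson formula summed
term by term; the rank-sum oracle enumerates group assignments.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def anova_theta(counts: np.ndarray) -> float:
    """W&C (1984) theta via literal nested-ANOVA sums of squares."""
    counts = np.asarray(counts, dtype=int)
    r = counts.shape[0]
    pairs = []
    for n0, n1, n2 in counts:
        inds = (
            [np.array([0, 0])] * n0
            + [np.array([0, 1])] * n1
            + [np.array([1, 1])] * n2
        )
        pairs.append(inds)
    n_i = np.array([len(p) for p in pairs])
    N = int(n_i.sum())
    if N == r:
        return float("nan")  # one individual per center: MS_I undefined
    allc = np.concatenate([np.concatenate(p) for p in pairs])
    ybar = allc.mean()
    if ybar in (0.0, 1.0):
        return float("nan")
    SS_G = SS_I = SS_P = 0.0
    for p in pairs:
        center_mean = np.concatenate(p).mean()
        for ind in p:
            SS_G += float(((ind - ind.mean()) ** 2).sum())
            SS_I += 2.0 * (ind.mean() - center_mean) ** 2
        SS_P += 2.0 * len(p) * (center_mean - ybar) ** 2
    MS_P = SS_P / (r - 1)
    MS_I = SS_I / (N - r)
    MS_G = SS_G / N
    nc = (N - (n_i**2).sum() / N) / (r - 1)
    a = (MS_P - MS_I) / (2 * nc)
    b = (MS_I - MS_G) / 2
    c = MS_G
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def exhaustive_max_theta(K: int, n: int, theta_fn) -> dict[int, float]:
    """Maximum theta over every genotype configuration, per minor-copy count."""
    per_center = [
        c for c in itertools.product(range(n + 1), repeat=3) if sum(c) == n
    ]
    best: dict[int, float] = {}
    for tab in itertools.product(per_center, repeat=K):
        counts = np.array(tab)
        alt = int((counts[:, 1] + 2 * counts[:, 2]).sum())
        m = min(alt, 2 * K * n - alt)
        if m == 0:
            continue
        th = theta_fn(counts)
        if not np.isnan(th):
            best[m] = max(best.get(m, -np.inf), th)
    return best


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-square of independence, summed cell by cell."""
    table = np.asarray(table, dtype=float)
    N = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = rows[i] * cols[j] / N
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def exact_rank_sum_p_two_sided(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by enumerating group assignments.

    Assumes no ties in the pooled sample.  Counts assignments whose
    rank-sum statistic is at least as extreme (in either tail) as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    nx = len(x)
    w_obs = ranks[:nx].sum()
    total = comb(len(pooled), nx)
    mean_w = nx * (len(pooled) + 1) / 2
    dev = abs(w_obs - mean_w)
    count = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= dev - 1e-12:
            count += 1
    return count / total
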