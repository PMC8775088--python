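"""Correspondence analysis of the population x sequencing-center table.

Quantifies sampling bias: whether each center sequenced the same
proportion of samples from each population.  The chi-square test of
independence gives the global answer; the SVD of the standardized-residual
matrix decomposes the departure into orthogonal dimensions whose principal
coordinates can be plotted as a biplot.  The total inertia (sum of squared
singular values) equals chi-square / N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = ["CAResult", "CorrespondenceAnalysis", "correspondence_analysis",
           "contingency_table"]


def contingency_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """Population x center sample counts from a metadata table."""
    return pd.crosstab(metadata["pop"], metadata["center"])


@dataclass
class CAResult:
    table: pd.DataFrame
    chi2: float
    dof: int
    pvalue: float
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia: np.ndarray
    total_inertia: float


class CorrespondenceAnalysis(TransformerMixin, BaseEstimator):
    """Sklearn-style CA transformer for a two-way contingency table.

    ``fit`` accepts the table (DataFrame or array of non-negative counts);
    rows or columns with a zero margin are dropped with a warning.  Fitted
    attributes: ``chi2_``, ``dof_``, ``pvalue_``, ``row_coords_``,
    ``col_coords_`` (principal coordinates), ``inertia_`` (squared singular
    values per dimension) and ``total_inertia_``.  ``transform`` projects
    supplementary row profiles onto the fitted dimensions.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        if (np.asarray(X) < 0).any():
            raise ValueError("contingency table must be non-negative")
        rz = X.sum(axis=1) == 0
        cz = X.sum(axis=0) == 0
        if rz.any() or cz.any():
            logger.warning("dropping zero-margin rows %s / columns %s",
                           list(X.index[rz]), list(X.columns[cz]))
            X = X.loc[~rz, ~cz]
        if X.shape[0] < 2 or X.shape[1] < 2:
            raise ValueError("need at least a 2x2 table after margin filtering")

        N = float(np.asarray(X).sum())
        P = np.asarray(X, dtype=float) / N
        r = P.sum(axis=1)
        c = P.sum(axis=0)
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        k_max = min(X.shape) - 1
        k = min(self.n_components or k_max, k_max)
        U, sv, Vt = U[:, :k], sv[:k], Vt[:k]

        chi2, pvalue, dof, _ = stats.chi2_contingency(np.asarray(X),
                                                      correction=False)
        dims = [f"dim{i + 1}" for i in range(k)]
        self.table_ = X
        self.n_ = N
        self.row_masses_, self.col_masses_ = r, c
        self.singular_values_ = sv
        self.components_ = Vt
        self.row_coords_ = pd.DataFrame(
            (U * sv) / np.sqrt(r)[:, None], index=X.index, columns=dims
        )
        self.col_coords_ = pd.DataFrame(
            (Vt.T * sv) / np.sqrt(c)[:, None], index=X.columns, columns=dims
        )
        self.inertia_ = sv**2
        self.total_inertia_ = float((S**2).sum())
        self.chi2_ = float(chi2)
        self.dof_ = int(dof)
        self.pvalue_ = float(pvalue)
        return self

    def transform(self, X):
        """Principal coordinates of supplementary rows (same columns)."""
        X = np.asarray(pd.DataFrame(X)[self.table_.columns], dtype=float)
        profiles = X / X.sum(axis=1, keepdims=True)
        return (profiles - self.col_masses_) / np.sqrt(self.col_masses_) @ \
            self.components_.T


def correspondence_analysis(table: pd.DataFrame,
                            n_components: int | None = None) -> CAResult:
    """Functional wrapper around :class:`CorrespondenceAnalysis`."""
    est = CorrespondenceAnalysis(n_components=n_components).fit(table)
    return CAResult(
        table=est.table_,
        chi2=est.chi2_,
        dof=est.dof_,
        pvalue=est.pvalue_,
        row_coords=est.row_coords_,
        col_coords=est.col_coords_,
        inertia=est.inertia_,
        total_inertia=est.total_inertia_,
    )
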