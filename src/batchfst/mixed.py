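"""Hierarchical mixed-model contrast for the sequencing-center effect.

The model is lmer-style: log(S) ~ center + (1 | continent/population),
i.e. a fixed sequencing-center effect on the log of a per-individual count
S, with nested random intercepts for continent and population-within-
continent.  Both the full model and the center-free null are fitted by
maximum likelihood (not REML — the two models differ in fixed effects, so
REML likelihoods would not be comparable) and compared with a
likelihood-ratio test on #centers - 1 degrees of freedom; the random-effect
structure is identical between the models, so no boundary mixture is
needed.

Only centers that sequenced samples in every population enter the
contrast, which keeps the center effect estimable free of center-by-
population confounding.  The reference center is the alphabetically first
one (absorbed in the intercept).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

__all__ = ["MixedModelResult", "CenterEffectModel", "fit_center_mixed_model"]


@dataclass
class MixedModelResult:
    """Fitted center contrast for one response (Tables-style layout)."""

    response: str
    reference_center: str
    centers_used: list[str]
    coefficients: pd.DataFrame  # index term; columns coef, se, z, p
    vc_continent: float
    vc_population: float
    llf_full: float
    llf_null: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    n_samples: int
    n_dropped_zero: int
    converged: bool

    def to_table(self) -> pd.DataFrame:
        out = self.coefficients.copy()
        out.columns = ["Coefficient", "Std. Error", "z value", "Pr(>|z|)"]
        return out


class CenterEffectModel(BaseEstimator):
    """Sklearn-style estimator for the mixed-model center contrast.

    Parameters
    ----------
    zero_policy : {"drop", "add_one", "error"}
        How to handle zero counts before taking logs.  ``drop`` (default)
        excludes those samples; ``add_one`` uses log(S + 1); ``error``
        refuses to fit.
    restrict_common_centers : bool
        Keep only centers present in every population (default True).

    Fitted attributes (trailing underscore) mirror
    :class:`MixedModelResult`; :meth:`fit` accepts a design frame ``X``
    with columns pop, super_pop and center, and a positive count vector
    ``y``.
    """

    def __init__(self, zero_policy: str = "drop",
                 restrict_common_centers: bool = True):
        self.zero_policy = zero_policy
        self.restrict_common_centers = restrict_common_centers

    def fit(self, X: pd.DataFrame, y):
        if self.zero_policy not in ("drop", "add_one", "error"):
            raise ValueError("zero_policy must be 'drop', 'add_one' or 'error'")
        data = X[["pop", "super_pop", "center"]].copy()
        y = np.asarray(y, dtype=float)
        if y.shape[0] != len(data):
            raise ValueError("X and y lengths differ")
        if (y < 0).any():
            raise ValueError("counts must be non-negative")
        zero = y == 0
        self.n_dropped_zero_ = 0
        if zero.any():
            if self.zero_policy == "error":
                raise ValueError(
                    f"{int(zero.sum())} samples have zero counts; set "
                    "zero_policy='add_one' (log(S+1)) or 'drop' to proceed"
                )
            if self.zero_policy == "drop":
                data = data.loc[~zero]
                y = y[~zero]
                self.n_dropped_zero_ = int(zero.sum())
        if self.zero_policy == "add_one":
            data["logS"] = np.log1p(y)
        else:
            data["logS"] = np.log(y)

        if self.restrict_common_centers:
            tab = pd.crosstab(data["pop"], data["center"])
            common = sorted(tab.columns[(tab > 0).all(axis=0)])
            dropped = sorted(set(data["center"]) - set(common))
            if dropped:
                logger.info("centers not present in every population dropped "
                            "from the contrast: %s", dropped)
            data = data[data["center"].isin(common)]
        centers = sorted(data["center"].unique())
        if len(centers) < 2:
            raise ValueError("fewer than two centers span all populations")
        self.centers_used_ = centers
        self.reference_center_ = centers[0]
        self.n_samples_ = len(data)

        if np.ptp(data["logS"].to_numpy()) == 0.0:
            # degenerate constant response: no variance to attribute
            terms = ["Intercept"] + [f"center[{c}]" for c in centers[1:]]
            coefs = pd.DataFrame(
                {"coef": [data["logS"].iloc[0]] + [0.0] * (len(centers) - 1),
                 "se": 0.0, "z": np.nan, "p": np.nan},
                index=terms,
            )
            self.coefficients_ = coefs
            self.vc_continent_ = 0.0
            self.vc_population_ = 0.0
            self.llf_ = self.llf_null_ = 0.0
            self.lrt_stat_, self.lrt_df_, self.lrt_p_ = 0.0, len(centers) - 1, 1.0
            self.converged_ = True
            return self

        full = self._fit_one("logS ~ C(center)", data)
        null = self._fit_one("logS ~ 1", data)

        params = full.params
        bse = full.bse
        terms, rows = [], []
        terms.append("Intercept")
        rows.append((params["Intercept"], bse["Intercept"]))
        for c in centers[1:]:
            key = f"C(center)[T.{c}]"
            terms.append(f"center[{c}]")
            rows.append((params[key], bse[key]))
        coef = pd.DataFrame(rows, columns=["coef", "se"], index=terms)
        with np.errstate(invalid="ignore", divide="ignore"):
            coef["z"] = coef["coef"] / coef["se"]
        coef["p"] = 2 * stats.norm.sf(np.abs(coef["z"]))

        self.coefficients_ = coef
        self.vc_continent_ = float(np.asarray(full.cov_re).ravel()[0])
        self.vc_population_ = float(full.vcomp[0]) if len(full.vcomp) else 0.0
        self.llf_ = float(full.llf)
        self.llf_null_ = float(null.llf)
        lrt = 2.0 * (self.llf_ - self.llf_null_)
        if lrt < 0:
            # numerical slack from imperfect optimisation of nested fits
            logger.warning("negative LRT statistic %.3g clipped to 0", lrt)
            lrt = 0.0
        self.lrt_stat_ = lrt
        self.lrt_df_ = len(centers) - 1
        self.lrt_p_ = float(stats.chi2.sf(lrt, self.lrt_df_))
        self.converged_ = bool(full.converged and null.converged)
        return self

    @staticmethod
    def _fit_one(formula: str, data: pd.DataFrame):
        model = smf.mixedlm(
            formula,
            data,
            groups="super_pop",
            re_formula="1",
            vc_formula={"pop": "0 + C(pop)"},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(reml=False, method=["lbfgs", "powell"], maxiter=500)
        return fit

    def result_(self, response: str = "S") -> MixedModelResult:
        return MixedModelResult(
            response=response,
            reference_center=self.reference_center_,
            centers_used=self.centers_used_,
            coefficients=self.coefficients_,
            vc_continent=self.vc_continent_,
            vc_population=self.vc_population_,
            llf_full=self.llf_,
            llf_null=self.llf_null_,
            lrt_stat=self.lrt_stat_,
            lrt_df=self.lrt_df_,
            lrt_p=self.lrt_p_,
            n_samples=self.n_samples_,
            n_dropped_zero=self.n_dropped_zero_,
            converged=self.converged_,
        )


def fit_center_mixed_model(
    counts: pd.DataFrame,
    response: str,
    zero_policy: str = "drop",
    restrict_common_centers: bool = True,
) -> MixedModelResult:
    """Fit the center contrast for one count column of a count table."""
    est = CenterEffectModel(
        zero_policy=zero_policy, restrict_common_centers=restrict_common_centers
    )
    est.fit(counts[["pop", "super_pop", "center"]], counts[response].to_numpy())
    return est.result_(response)
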