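"""Population-averaged (GEE) comparisons of yearly cross-sections.

Marginal models for the 2017-vs-2019 contrasts: Gaussian/identity for BMI,
binomial/logit for obesity prevalence and WMT utilization, estimated with
generalized estimating equations clustered on patient with an exchangeable
working correlation, and summarized with average marginal effects (AME).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MarginalFit", "fit_marginal_model", "average_marginal_effect"]

ADJUSTMENT_COVARIATES = ("age", "sex", "race", "ethnicity")


@dataclass
class MarginalFit:
    """A fitted GEE with its design metadata."""

    result: object  # statsmodels GEEResults
    outcome: str
    family: str
    adjusted: bool
    n_patients: int
    n_obs: int
    data: pd.DataFrame
    formula: str

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def robust_cov(self) -> np.ndarray:
        cov = np.asarray(self.result.cov_params())
        return 0.5 * (cov + cov.T)


def fit_marginal_model(
    cross_sections: pd.DataFrame,
    outcome: str,
    adjusted: bool = False,
) -> MarginalFit:
    """Fit the year-contrast GEE on stacked yearly cross-sections.

    ``cross_sections`` holds one row per patient-year with columns
    ``patient_id``, ``year``, the outcome, and (for adjusted models) age,
    sex, race and ethnicity. Continuous outcomes (``bmi``) use a Gaussian
    family with identity link; binary outcomes a binomial family with logit
    link. Patients contributing both years form clusters with exchangeable
    working correlation; robust (sandwich) standard errors are returned.
    """
    df = cross_sections.copy()
    years = sorted(df["year"].unique())
    if len(years) < 2:
        raise ValueError("cross-sections must span at least two years")
    if outcome not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not found")

    binary = set(pd.unique(df[outcome].dropna())) <= {0, 1, 0.0, 1.0, True, False}
    family = sm.families.Binomial() if binary else sm.families.Gaussian()
    terms = ["C(year)"]
    if adjusted:
        terms += [
            c if c == "age" else f"C({c})"
            for c in ADJUSTMENT_COVARIATES
            if c in df.columns
        ]
    formula = f"{outcome} ~ " + " + ".join(terms)
    df = df.sort_values(["patient_id", "year"]).reset_index(drop=True)
    model = sm.GEE.from_formula(
        formula,
        groups="patient_id",
        data=df,
        family=family,
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit()
    return MarginalFit(
        result=result,
        outcome=outcome,
        family="binomial/logit" if binary else "gaussian/identity",
        adjusted=adjusted,
        n_patients=df["patient_id"].nunique(),
        n_obs=len(df),
        data=df,
        formula=formula,
    )


def average_marginal_effect(
    fit: MarginalFit, contrast: tuple = ("year", None, None), z: float = 1.96
) -> dict:
    """AME of the year contrast with a delta-method CI.

    AME = mean over all observations of [prediction with year set to the
    later level minus prediction with year set to the earlier level]; the
    variance comes from the numerical gradient of that average with respect
    to the coefficients, sandwiched with the robust covariance.
    """
    name, lo_level, hi_level = contrast
    levels = sorted(fit.data[name].unique())
    lo_level = levels[0] if lo_level is None else lo_level
    hi_level = levels[-1] if hi_level is None else hi_level

    import patsy

    model = fit.result.model
    d_hi = fit.data.copy()
    d_hi[name] = hi_level
    d_lo = fit.data.copy()
    d_lo[name] = lo_level
    design_info = model.data.design_info
    X_hi = np.asarray(patsy.build_design_matrices([design_info], d_hi)[0])
    X_lo = np.asarray(patsy.build_design_matrices([design_info], d_lo)[0])
    link_inv = model.family.link.inverse
    beta = np.asarray(fit.params)

    def ame_at(b):
        return float(np.mean(link_inv(X_hi @ b) - link_inv(X_lo @ b)))

    ame = ame_at(beta)
    grad = np.empty_like(beta)
    for j in range(len(beta)):
        h = 1e-6 * max(1.0, abs(beta[j]))
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h
        bm[j] -= h
        grad[j] = (ame_at(bp) - ame_at(bm)) / (2 * h)
    se = float(np.sqrt(grad @ fit.robust_cov @ grad))
    return {"ame": ame, "se": se, "lo": ame - z * se, "hi": ame + z * se}
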