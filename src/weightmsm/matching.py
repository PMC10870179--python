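"""Propensity-score estimation and stratified 1:1 optimal matching.

Exposed patients are matched to unexposed comparators within 16 strata
(sex x majority race x majority ethnicity x any weight-related condition)
by minimum-total-distance bipartite assignment on the absolute difference of
logit propensity scores, then checked for covariate balance with
standardized mean differences (|SMD| < 0.1 criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

__all__ = [
    "MatchResult",
    "fit_propensity",
    "match_stratified",
    "balance_table",
    "greedy_match_total_distance",
]

DEFAULT_PROPENSITY_COVARIATES = (
    "followup_days",
    "age",
    "bmi",
    "female",
    "hyperlipidemia",
    "hypertension",
    "nafld",
    "osa",
    "t2d",
)


def fit_propensity(
    cohort: pd.DataFrame,
    covariates=DEFAULT_PROPENSITY_COVARIATES,
    exposure_col: str = "exposed",
) -> pd.Series:
    """Logistic propensity for WMT exposure; returns fitted probabilities.

    Constant covariate columns are dropped with a warning. Complete
    separation surfaces as a convergence error naming the model.
    """
    if exposure_col not in cohort.columns:
        raise KeyError(f"exposure column {exposure_col!r} missing")
    cols = [c for c in covariates if c in cohort.columns]
    X = cohort[cols].astype(float)
    keep = [c for c in cols if X[c].nunique() > 1]
    dropped = sorted(set(cols) - set(keep))
    if dropped:
        warnings.warn(f"dropping constant propensity covariates: {dropped}", stacklevel=2)
    X = sm.add_constant(X[keep], has_constant="add")
    y = cohort[exposure_col].astype(float)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparation or numerical failure
        raise RuntimeError(f"propensity model failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("propensity model failed to converge: non-finite coefficients")
    scores = pd.Series(np.asarray(res.predict(X)), index=cohort.index, name="propensity")
    scores.attrs["params"] = res.params
    scores.attrs["bse"] = res.bse
    return scores


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


@dataclass
class MatchResult:
    """1:1 matched pairs with strata, scores, and distances.

    ``unmatchable`` reports strata that had more exposed than controls (only
    populated when matching ran with ``on_unmatchable='report'``).
    """

    pairs: pd.DataFrame  # exposed_id, control_id, stratum, distance
    total_distance: float
    n_strata: int
    unmatchable: list = None

    @property
    def exposed_ids(self):
        return self.pairs["exposed_id"].to_numpy()

    @property
    def control_ids(self):
        return self.pairs["control_id"].to_numpy()


def match_stratified(
    cohort: pd.DataFrame,
    score_col: str = "propensity",
    stratum_cols=("female", "race_majority", "ethnicity_majority", "any_condition"),
    exposure_col: str = "exposed",
    id_col: str = "patient_id",
    on_unmatchable: str = "raise",
) -> MatchResult:
    """Minimum-total-distance 1:1 matching within strata.

    Within each stratum (the cross of the listed binary columns), exposed
    patients are assigned to distinct controls minimizing the total
    |logit(score) difference| (optimal rectangular assignment). A stratum
    with more exposed than available controls raises an error listing the
    counts, or — with ``on_unmatchable='report'`` — is skipped and listed
    in the result's ``unmatchable`` report.
    """
    if on_unmatchable not in ("raise", "report"):
        raise ValueError("on_unmatchable must be 'raise' or 'report'")
    df = cohort.copy()
    missing = [c for c in (score_col, exposure_col, id_col) if c not in df.columns]
    if missing:
        raise KeyError(f"missing columns: {missing}")
    strata = df.groupby(list(stratum_cols), sort=True)
    shortfalls = []
    rows = []
    for key, grp in strata:
        exp = grp[grp[exposure_col] == 1]
        ctl = grp[grp[exposure_col] == 0]
        if len(exp) == 0:
            continue
        if len(ctl) < len(exp):
            shortfalls.append((key, len(exp), len(ctl)))
            continue
        le = _logit(exp[score_col].to_numpy())
        lc = _logit(ctl[score_col].to_numpy())
        cost = np.abs(le[:, None] - lc[None, :])
        ri, ci = linear_sum_assignment(cost)
        for r, c in zip(ri, ci):
            rows.append(
                dict(
                    exposed_id=exp[id_col].iloc[r],
                    control_id=ctl[id_col].iloc[c],
                    stratum=str(key),
                    distance=float(cost[r, c]),
                )
            )
    if shortfalls and on_unmatchable == "raise":
        detail = "; ".join(
            f"stratum {k}: {ne} exposed vs {nc} controls" for k, ne, nc in shortfalls
        )
        raise ValueError(f"unmatchable strata (more exposed than controls): {detail}")
    pairs = pd.DataFrame(rows, columns=["exposed_id", "control_id", "stratum", "distance"])
    return MatchResult(
        pairs=pairs,
        total_distance=float(pairs["distance"].sum()) if len(pairs) else 0.0,
        n_strata=pairs["stratum"].nunique() if len(pairs) else 0,
        unmatchable=[
            dict(stratum=str(k), n_exposed=ne, n_controls=nc) for k, ne, nc in shortfalls
        ],
    )


def greedy_match_total_distance(
    cohort: pd.DataFrame,
    score_col: str = "propensity",
    stratum_cols=("female", "race_majority", "ethnicity_majority", "any_condition"),
    exposure_col: str = "exposed",
) -> float:
    """Total distance of greedy nearest-neighbor matching (comparison oracle).

    Processes exposed patients in score order, each taking its nearest
    remaining control in the stratum; used to check that optimal matching
    never does worse.
    """
    total = 0.0
    for _, grp in cohort.groupby(list(stratum_cols), sort=True):
        exp = grp[grp[exposure_col] == 1]
        ctl = grp[grp[exposure_col] == 0]
        if len(exp) == 0:
            continue
        if len(ctl) < len(exp):
            raise ValueError("more exposed than controls in a stratum")
        le = _logit(exp[score_col].to_numpy())
        lc = list(_logit(ctl[score_col].to_numpy()))
        for v in sorted(le):
            j = int(np.argmin(np.abs(np.asarray(lc) - v)))
            total += abs(lc[j] - v)
            lc.pop(j)
    return float(total)


def balance_table(
    cohort: pd.DataFrame,
    covariates,
    exposure_col: str = "exposed",
    pairs: pd.DataFrame | None = None,
    id_col: str = "patient_id",
) -> pd.DataFrame:
    """Standardized mean differences between exposed and control groups.

    SMD = (mean_exposed - mean_control) / pooled SD, the pooled SD being the
    root mean of the two group variances (for binary covariates this is the
    usual proportion-based version). With ``pairs`` given, the table is
    computed on the matched subset. Zero pooled SD yields SMD 0 with a
    warning. A ``max_abs_smd`` attribute summarizes the table.
    """
    df = cohort
    if pairs is not None:
        keep = set(pairs["exposed_id"]) | set(pairs["control_id"])
        df = cohort[cohort[id_col].isin(keep)]
    rows = []
    for c in covariates:
        a = df.loc[df[exposure_col] == 1, c].astype(float)
        b = df.loc[df[exposure_col] == 0, c].astype(float)
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        if pooled == 0 or not np.isfinite(pooled):
            warnings.warn(f"zero pooled SD for {c!r}; SMD set to 0", stacklevel=2)
            smd = 0.0
        else:
            smd = float((a.mean() - b.mean()) / pooled)
        rows.append(dict(covariate=c, mean_exposed=a.mean(), mean_control=b.mean(), smd=smd))
    out = pd.DataFrame(rows)
    out.attrs["max_abs_smd"] = float(out["smd"].abs().max()) if len(out) else 0.0
    return out
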