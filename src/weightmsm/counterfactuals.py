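"""Population-level counterfactuals: AME, attributable fraction, scenarios.

Comparisons of the population-average model-based 1-year probability of >=5%
weight loss under observed WMT exposure against counterfactuals: no WMT (the
average marginal effect, AME, and the population attributable fraction,
PAF = AME / observed mean), one WMT zeroed at a time, and fold-increase
utilization scenarios with their loss-vs-gain tipping point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PanelDataset, PatientPanel
from .msm import MSMFit, MSMParams, interval_probability
from .prediction import HORIZON_DAYS, simulate_parameter_uncertainty

__all__ = [
    "patient_level_prob",
    "population_ame",
    "attributable_fraction",
    "fold_increase_scenarios",
    "tipping_point_summary",
    "CounterfactualSummary",
    "counterfactual_summary",
]

WMT_GROUPS = ("nutrition", "mr", "aom", "surgery")


def _segments_key(patient: PatientPanel, structure, horizon, zero):
    timeline = patient.exposure if zero is None else patient.exposure.zeroed(
        None if zero == "all" else zero
    )
    segs = timeline.segments_between(0.0, horizon)
    base = tuple(
        (name, round(float(patient.baseline[name]), 10))
        for name in structure.covariates
        if name in patient.baseline
    )
    key = (base, tuple((round(dt, 6), tuple(vec)) for dt, vec in segs))
    cols = timeline.columns
    merged = []
    for dt, vec in segs:
        z = dict(zip(cols, vec))
        z.update({k: v for k, v in base})
        merged.append((z, dt))
    return key, merged


def _group_probs(params, structure, patients, horizon, zero, cache):
    """Per-patient (P(loss states), P(gain states)) from baseline at horizon."""
    loss = np.empty(len(patients))
    gain = np.empty(len(patients))
    for i, p in enumerate(patients):
        key, segments = _segments_key(p, structure, horizon, zero)
        if key not in cache:
            P = interval_probability(params, segments, structure)
            cache[key] = (float(P[2, 0] + P[2, 1]), float(P[2, 3] + P[2, 4]))
        loss[i], gain[i] = cache[key]
    return loss, gain


def patient_level_prob(
    fit,
    patient: PatientPanel,
    horizon: float = HORIZON_DAYS,
    zero: str | None = None,
) -> float:
    """P(>=5% loss at ``horizon``) from baseline through actual exposures.

    Propagates from the baseline state through the patient's exposure
    segments during days 0..horizon (changepoint-split products of matrix
    exponentials) and returns p1 + p2. ``zero`` discards one WMT group
    ('nutrition', 'mr', 'aom', 'surgery') or all of them ('all'). Requires
    the patient to be followed at least ``horizon`` days.
    """
    if patient.times[-1] < horizon:
        raise ValueError("patient follow-up is shorter than the horizon")
    params, structure = _resolve(fit)
    loss, _ = _group_probs(params, structure, [patient], horizon, zero, {})
    return float(loss[0])


def _resolve(fit):
    if isinstance(fit, MSMFit):
        return fit.params, fit.structure
    return fit


def _full_followup(cohort: PanelDataset, horizon: float) -> list:
    return [p for p in cohort.patients if p.times[-1] >= horizon]


def population_ame(
    fit: MSMFit,
    cohort: PanelDataset,
    which: str = "all",
    horizon: float = HORIZON_DAYS,
    B: int = 0,
    seed: int = 0,
) -> dict:
    """Population AME of WMT on P(>=5% loss at 1 year), with optional CI.

    AME = mean over patients (with >= ``horizon`` days of follow-up) of
    [P(loss | observed exposures) - P(loss | exposures in ``which`` zeroed)].
    ``which='all'`` zeroes every WMT; a group name zeroes that WMT only.
    With B > 0, a percentile CI from MVN parameter simulation is included.
    """
    patients = _full_followup(cohort, horizon)
    if not patients:
        raise ValueError("no patients with full follow-up")
    zero = "all" if which == "all" else which

    def functional(params):
        cache: dict = {}
        obs, _ = _group_probs(params, fit.structure, patients, horizon, None, cache)
        cf, _ = _group_probs(params, fit.structure, patients, horizon, zero, cache)
        return np.array([obs.mean(), cf.mean(), obs.mean() - cf.mean()])

    obs_mean, cf_mean, ame = functional(fit.params)
    out = {
        "which": which,
        "observed_mean": float(obs_mean),
        "counterfactual_mean": float(cf_mean),
        "ame": float(ame),
        "n": len(patients),
    }
    if B > 0:
        ci = simulate_parameter_uncertainty(fit, lambda p: functional(p)[2], B=B, seed=seed)
        out["lo"], out["hi"] = ci["lo"], ci["hi"]
    return out


def attributable_fraction(ame: float, observed_mean: float) -> float:
    """PAF = AME / observed population-average probability, in percent.

    Both arguments must be on the same scale (both fractions or both
    percents); the result is their ratio expressed as a percentage.
    """
    if observed_mean <= 0:
        raise ZeroDivisionError("PAF undefined: observed mean probability is 0")
    return 100.0 * ame / observed_mean


def fold_increase_scenarios(
    fit: MSMFit,
    cohort: PanelDataset,
    multipliers=(2, 3, 4, 5),
    mode: str = "linear",
    fold_convention: str = "multiply",
    horizon: float = HORIZON_DAYS,
    B: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Scenario table for hypothetical increases in WMT utilization.

    In the default linear-extrapolation mode the per-patient WMT
    contribution is scaled: p_i(m) = p_i(no WMT) + m * [p_i(observed) -
    p_i(no WMT)], clipped to [0, 1], then averaged — so the per-fold
    increment of the population mean is constant and equals the AME.
    ``fold_convention='increase-by'`` reads a "k-fold increase" as
    utilization multiplied by k+1. The resampling mode instead replicates
    exposed patients' exposure histories onto randomly chosen unexposed
    patients (m-1 more times) and recomputes the means.

    Columns: multiplier, mean_loss, mean_gain, diff (loss - gain), rr
    (loss / gain), each with percentile CI columns when B > 0.
    """
    if any(m < 0 for m in multipliers):
        raise ValueError("multipliers must be nonnegative")
    if mode not in ("linear", "resampling"):
        raise ValueError("mode must be 'linear' or 'resampling'")
    patients = _full_followup(cohort, horizon)
    eff = [m + 1 if fold_convention == "increase-by" else m for m in multipliers]
    if fold_convention not in ("multiply", "increase-by"):
        raise ValueError("fold_convention must be 'multiply' or 'increase-by'")

    if mode == "linear":

        def scenario_stats(params):
            cache: dict = {}
            l1, g1 = _group_probs(params, fit.structure, patients, horizon, None, cache)
            l0, g0 = _group_probs(params, fit.structure, patients, horizon, "all", cache)
            out = []
            for m in eff:
                lm = np.clip(l0 + m * (l1 - l0), 0.0, 1.0).mean()
                gm = np.clip(g0 + m * (g1 - g0), 0.0, 1.0).mean()
                out.extend([lm, gm])
            return np.array(out)

    else:
        exposed_idx = [
            i for i, p in enumerate(patients) if np.any(p.exposure.values != 0)
        ]
        unexposed_idx = [i for i in range(len(patients)) if i not in set(exposed_idx)]
        rng = np.random.default_rng(seed + 7)
        assignments = {}
        for m in eff:
            extra = int(round((m - 1) * len(exposed_idx)))
            if extra <= 0:
                assignments[m] = []
                continue
            replace = extra > len(unexposed_idx)
            targets = rng.choice(unexposed_idx, size=extra, replace=replace)
            donors = rng.choice(exposed_idx, size=extra, replace=True)
            assignments[m] = list(zip(targets, donors))

        def scenario_stats(params):
            cache: dict = {}
            l1, g1 = _group_probs(params, fit.structure, patients, horizon, None, cache)
            out = []
            for m in eff:
                lm, gm = l1.copy(), g1.copy()
                for tgt, donor in assignments[m]:
                    hybrid = PatientPanel(
                        patients[tgt].patient_id,
                        patients[tgt].times,
                        patients[tgt].states,
                        patients[tgt].baseline,
                        patients[donor].exposure,
                    )
                    l, g = _group_probs(params, fit.structure, [hybrid], horizon, None, cache)
                    lm[tgt], gm[tgt] = l[0], g[0]
                out.extend([lm.mean(), gm.mean()])
            return np.array(out)

    stats = scenario_stats(fit.params)
    if B > 0:
        ci = simulate_parameter_uncertainty(fit, scenario_stats, B=B, seed=seed)
        lo, hi = ci["lo"], ci["hi"]
        draws = ci["draws"]
    rows = []
    for j, (m_in, m) in enumerate(zip(multipliers, eff)):
        lm, gm = stats[2 * j], stats[2 * j + 1]
        row = dict(
            multiplier=m_in,
            effective_multiplier=m,
            mean_loss=lm,
            mean_gain=gm,
            diff=lm - gm,
            rr=lm / gm if gm > 0 else np.inf,
        )
        if B > 0:
            dl = draws[:, 2 * j] - draws[:, 2 * j + 1]
            with np.errstate(divide="ignore", invalid="ignore"):
                dr = draws[:, 2 * j] / draws[:, 2 * j + 1]
            row.update(
                loss_lo=lo[2 * j],
                loss_hi=hi[2 * j],
                gain_lo=lo[2 * j + 1],
                gain_hi=hi[2 * j + 1],
                diff_lo=float(np.percentile(dl, 2.5)),
                diff_hi=float(np.percentile(dl, 97.5)),
                rr_lo=float(np.nanpercentile(dr, 2.5)),
                rr_hi=float(np.nanpercentile(dr, 97.5)),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def tipping_point_summary(scenarios: pd.DataFrame) -> dict:
    """Smallest multiplier at which >=5% loss overtakes >=5% gain.

    Flags the smallest multiplier whose loss-gain difference is positive and
    whose CI (when present) excludes 0; with no CI columns the point
    estimate alone decides. Returns the annotated table and the flagged
    multiplier (None when loss never significantly exceeds gain).
    """
    if len(scenarios) < 2:
        raise ValueError("scenario table must span at least 2 multipliers")
    df = scenarios.sort_values("multiplier").reset_index(drop=True)
    has_ci = "diff_lo" in df.columns
    if has_ci:
        flagged = df[(df["diff"] > 0) & (df["diff_lo"] > 0)]
    else:
        flagged = df[df["diff"] > 0]
    tip = None if len(flagged) == 0 else flagged["multiplier"].iloc[0]
    return {"tipping_multiplier": tip, "table": df}


@dataclass
class CounterfactualSummary:
    """Observed vs counterfactual population probabilities and scenarios."""

    observed_mean: float
    no_wmt_mean: float
    ame: float
    paf_pct: float
    per_wmt: dict
    scenarios: pd.DataFrame
    tipping_multiplier: object
    n: int
    ci: dict = field(default_factory=dict)


def counterfactual_summary(
    fit: MSMFit,
    cohort: PanelDataset,
    multipliers=(2, 3, 4, 5),
    horizon: float = HORIZON_DAYS,
    B: int = 0,
    seed: int = 0,
    per_wmt: bool = True,
) -> CounterfactualSummary:
    """Full population counterfactual analysis in one call."""
    overall = population_ame(fit, cohort, "all", horizon, B=B, seed=seed)
    per = {}
    if per_wmt:
        for w in WMT_GROUPS:
            per[w] = population_ame(fit, cohort, w, horizon, B=0)
    scen = fold_increase_scenarios(
        fit, cohort, multipliers, horizon=horizon, B=B, seed=seed
    )
    tip = tipping_point_summary(scen)
    return CounterfactualSummary(
        observed_mean=overall["observed_mean"],
        no_wmt_mean=overall["counterfactual_mean"],
        ame=overall["ame"],
        paf_pct=attributable_fraction(overall["ame"], overall["observed_mean"]),
        per_wmt=per,
        scenarios=scen,
        tipping_multiplier=tip["tipping_multiplier"],
        n=overall["n"],
        ci={k: overall[k] for k in ("lo", "hi") if k in overall},
    )
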