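"""Synthetic EHR generator with known ground-truth weight dynamics.

Emulates the raw material of a primary-care weight-trajectory study: a
cohort of patients whose latent weight status follows a five-state
birth-death continuous-time Markov chain with proportional intensities, whose
weights are observed only at irregular clinic visits (panel observation), and
whose weight-management-treatment (WMT) exposures follow event streams
(dietitian visits, meal-replacement program visits, medication order
intervals, a surgery date) that the cohort builder re-codes into time-varying
exposure indicators.

Treatment uptake is logistic in baseline covariates, which deliberately
confounds exposure with case mix so the propensity-matching stage has
something to remove. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_LADDER,
    RawEHRBundle,
    StateLadder,
    build_exposure_segments,
)
from .msm import (
    MSMParams,
    N_STATES,
    TRANSITIONS,
    TransitionStructure,
    build_intensity_matrix,
)

__all__ = [
    "StatePath",
    "SimConfig",
    "UptakeModel",
    "default_structure",
    "default_true_params",
    "simulate_ctmc_path",
    "emit_weights",
    "simulate_population",
]


@dataclass
class StatePath:
    """A realized latent trajectory: sojourn states and jump times (days)."""

    jump_times: np.ndarray  # strictly increasing, within (0, horizon]
    states: np.ndarray  # one per sojourn; len(states) == len(jump_times) + 1
    horizon: float

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.states) != len(self.jump_times) + 1:
            raise ValueError("need exactly one more sojourn state than jumps")
        if len(self.jump_times) and np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if np.any(np.abs(np.diff(self.states)) != 1):
            raise ValueError("consecutive states must be adjacent")

    def state_at(self, t) -> np.ndarray:
        """State occupied at time(s) t; errors beyond the simulated horizon."""
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(tt > self.horizon) or np.any(tt < 0):
            raise ValueError("query time outside simulated horizon")
        idx = np.searchsorted(self.jump_times, tt, side="right")
        out = self.states[idx]
        return out if np.ndim(t) else int(out[0])


def _validate_generator(Q: np.ndarray, tol: float = 1e-8) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError("intensity matrix must be 5x5")
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -tol):
        raise ValueError("invalid intensity matrix: negative off-diagonal")
    if np.any(np.abs(Q.sum(axis=1)) > tol):
        raise ValueError("invalid intensity matrix: rows must sum to 0")


def simulate_ctmc_path(segments, init_state: int, rng: np.random.Generator) -> StatePath:
    """Exact (Gillespie-style) CTMC path under piecewise-constant intensities.

    ``segments`` is a list of (duration_days, Q) in time order. Within a
    segment, the sojourn time in state s is exponential with rate -Q[s, s];
    at a segment boundary the clock restarts with the new matrix, which is
    exact by memorylessness of the exponential.
    """
    for dur, Q in segments:
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        _validate_generator(Q)
    t = 0.0
    state = int(init_state)
    jump_times, states = [], [state]
    for dur, Q in segments:
        seg_end = t + dur
        Q = np.asarray(Q, dtype=float)
        while True:
            rate = -Q[state - 1, state - 1]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if t + wait >= seg_end:
                break
            t += wait
            probs = np.clip(Q[state - 1], 0, None)
            probs[state - 1] = 0.0
            probs = probs / probs.sum()
            state = int(rng.choice(N_STATES, p=probs)) + 1
            jump_times.append(t)
            states.append(state)
        t = seg_end
    return StatePath(np.array(jump_times), np.array(states), horizon=t)


#: Relative-weight band sampled for each state (open intervals; the
#: open-ended loss/gain states are truncated at +/-20% of baseline).
STATE_BANDS = {1: (0.80, 0.90), 2: (0.90, 0.95), 3: (0.95, 1.05), 4: (1.05, 1.10), 5: (1.10, 1.20)}
_BAND_MARGIN = 1e-6


def emit_weights(
    path: StatePath,
    baseline_weight: float,
    visit_days,
    rng: np.random.Generator,
    ladder: StateLadder = DEFAULT_LADDER,
) -> np.ndarray:
    """Back-calculate observed weights from the latent state at each visit.

    Each weight is uniform on the open relative-weight band of the occupied
    state (a small margin keeps draws strictly off band boundaries, so the
    state coding of the emitted weight round-trips exactly). A visit at day 0
    returns the baseline weight itself.
    """
    if baseline_weight <= 0:
        raise ValueError("baseline_weight must be positive")
    days = np.atleast_1d(np.asarray(visit_days, dtype=float))
    states = path.state_at(days)
    lo = np.array([STATE_BANDS[s][0] for s in np.atleast_1d(states)])
    hi = np.array([STATE_BANDS[s][1] for s in np.atleast_1d(states)])
    rel = rng.uniform(lo + _BAND_MARGIN, hi - _BAND_MARGIN)
    rel = np.where(days == 0.0, 1.0, rel)
    w = baseline_weight * rel
    return w if np.ndim(visit_days) else float(w[0])


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------


def default_structure(demographics: tuple[str, ...] = ()) -> TransitionStructure:
    """Exposure-only structure: the four WMT indicators on all 8 transitions.

    Surgery is carried as a single "any recent surgery" style pooled effect
    via the granular bins sharing one coefficient pattern; for ground-truth
    simulation a single coefficient per WMT per direction is sufficient and
    keeps the recovery experiments well identified.
    """
    covariates = tuple(demographics) + (
        "nutrition_90d",
        "mr_early_active",
        "mr_late_active",
        "aom_any",
        "surg_0_90",
        "surg_91_180",
        "surg_181_364",
        "surg_ge365",
    )
    mask = np.ones((len(TRANSITIONS), len(covariates)), dtype=bool)
    return TransitionStructure(covariates, mask)


#: Baseline per-day intensities calibrated so that, with no WMT exposure,
#: the 364-day state distribution from baseline approximates the reference
#: no-treatment profile (about 5% with >=10% loss, 16% with >=5% loss, 68%
#: stable, 16% with >=5% gain). TRANSITIONS order: loss-direction
#: (2->1, 3->2, 4->3, 5->4) then gain-direction (1->2, 2->3, 3->4, 4->5).
DEFAULT_LOG_Q0 = np.log(
    [0.002464, 0.001677, 0.004788, 0.001175, 0.003217, 0.009783, 0.001111, 0.001836]
)

#: Ground-truth WMT hazard ratios (loss-direction, gain-direction): modest
#: for nutrition counseling, strong for the meal-replacement early phase and
#: surgery, intermediate for medication, consistent with the qualitative
#: ordering reported for these treatments.
DEFAULT_TRUE_HR = {
    "nutrition_90d": (1.35, 0.80),
    "mr_early_active": (6.0, 0.55),
    "mr_late_active": (1.4, 0.70),
    "aom_any": (1.55, 0.72),
    "surg_0_90": (12.0, 0.15),
    "surg_91_180": (6.0, 0.15),
    "surg_181_364": (2.5, 0.20),
    "surg_ge365": (1.5, 0.30),
}


def default_true_params(
    structure: TransitionStructure | None = None,
    hr_overrides: dict | None = None,
    log_q0: np.ndarray | None = None,
) -> tuple[MSMParams, TransitionStructure]:
    """Ground-truth parameters on a given (default: exposure-only) structure.

    ``hr_overrides`` maps covariate name -> (loss-direction HR,
    gain-direction HR) applied uniformly within each direction.
    """
    structure = structure or default_structure()
    hrs = dict(DEFAULT_TRUE_HR)
    if hr_overrides:
        hrs.update(hr_overrides)
    beta = np.zeros((len(TRANSITIONS), structure.n_covariates))
    for j, name in enumerate(structure.covariates):
        if name in hrs:
            loss_hr, gain_hr = hrs[name]
            beta[:4, j] = np.log(loss_hr)
            beta[4:, j] = np.log(gain_hr)
    beta[~structure.mask] = 0.0
    lq = DEFAULT_LOG_Q0.copy() if log_q0 is None else np.asarray(log_q0, float)
    return MSMParams(lq, beta), structure


@dataclass
class UptakeModel:
    """Logistic uptake of one WMT with event-stream timing.

    logit P(uptake) = logit(prob) + bmi_coef*(BMI-30)/5 + cond_coef*any_condition,
    creating confounding by case mix. ``start_window`` (days) places the
    first event uniformly; visits recur every ``visit_interval`` days for
    ``duration`` days (medication orders are one interval; surgery a single
    date).
    """

    prob: float = 0.0
    bmi_coef: float = 0.5
    cond_coef: float = 0.5
    start_window: tuple[float, float] = (0.0, 540.0)
    duration: float = 365.0
    visit_interval: float = 45.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("uptake probability must be in [0, 1]")


def _default_uptake() -> dict:
    # prospective uptake shares among patients with obesity: ~6% nutrition,
    # ~0.4% meal replacement, ~2.6% medication, ~1% surgery
    return {
        "nutrition": UptakeModel(prob=0.063),
        "mr": UptakeModel(prob=0.004, visit_interval=30.0, duration=365.0),
        "aom": UptakeModel(prob=0.026, duration=365.0),
        "surgery": UptakeModel(prob=0.010, start_window=(90.0, 540.0)),
    }


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic cohort.

    Defaults emulate the source setting: mean age ~50, ~57% female, mean
    baseline BMI 35 (SD 5, truncated at 30 so the trajectory cohort is a
    cohort with obesity), ~4 weight-bearing visits per year over ~3 years of
    follow-up, and low WMT uptake.
    """

    n_patients: int = 1000
    followup_days: float = 1095.0
    visit_rate: float = 4.0  # expected visits per year
    exposure_uptake: dict = field(default_factory=_default_uptake)
    true_params: MSMParams | None = None
    structure: TransitionStructure | None = None
    age_mean: float = 50.0
    age_sd: float = 15.0
    female_prob: float = 0.57
    race_majority_prob: float = 0.79
    hispanic_prob: float = 0.03
    condition_prevalence: dict = field(
        default_factory=lambda: {
            "t2d": 0.05,
            "hyperlipidemia": 0.09,
            "hypertension": 0.15,
            "nafld": 0.015,
            "osa": 0.01,
        }
    )
    bmi_mean: float = 35.0
    bmi_sd: float = 5.0
    bmi_min: float = 30.0
    height_mean: float = 1.68
    height_sd: float = 0.09
    entry_start: str = "2017-01-01"
    entry_span_days: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be positive")
        for p in [self.female_prob, self.race_majority_prob, self.hispanic_prob] + list(
            self.condition_prevalence.values()
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.true_params is None:
            self.true_params, self.structure = default_true_params(self.structure)


_WMT_DRUGS = ("phentermine", "topiramate", "orlistat", "naltrexone_bupropion", "glp1ra")


def _uptake_events(name: str, model: UptakeModel, bmi: float, any_cond: float,
                   followup: float, rng) -> list[dict]:
    """Draw one patient's event stream for one WMT (possibly empty)."""
    if model.prob <= 0.0:
        return []
    base_logit = np.log(model.prob / (1 - model.prob))
    eta = base_logit + model.bmi_coef * (bmi - 30.0) / 5.0 + model.cond_coef * any_cond
    if rng.random() >= 1.0 / (1.0 + np.exp(-eta)):
        return []
    lo, hi = model.start_window
    start = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    if start >= followup:
        start = max(0.0, followup - 1.0)
    events = []
    if name == "nutrition":
        d = start
        while d < min(start + model.duration, followup):
            events.append(dict(kind="nutrition_visit", day=d, end_day=np.nan, drug=""))
            d += model.visit_interval
    elif name == "mr":
        d = start
        while d < min(start + model.duration, followup):
            events.append(dict(kind="mr_visit", day=d, end_day=np.nan, drug=""))
            d += model.visit_interval
    elif name == "aom":
        drug = _WMT_DRUGS[int(rng.integers(len(_WMT_DRUGS)))]
        events.append(
            dict(kind="aom_order", day=start, end_day=min(start + model.duration, followup), drug=drug)
        )
    elif name == "surgery":
        events.append(dict(kind="surgery", day=start, end_day=np.nan, drug=""))
    return events


def simulate_population(config: SimConfig) -> RawEHRBundle:
    """Simulate linked raw tables for a panel-observed weight cohort.

    For each patient: draw demographics and baseline weight; draw WMT event
    streams from the uptake models; code the events into the exposure
    timeline with the same rules the cohort builder applies (so latent
    dynamics and downstream exposure coding agree by construction); simulate
    the latent state path under the ground-truth intensities; emit weights
    at Poisson-process visit dates. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    params, structure = config.true_params, config.structure
    entry0 = pd.Timestamp(config.entry_start)
    T = float(config.followup_days)

    pat_rows, visit_rows, weight_rows, event_rows, cond_rows = [], [], [], [], []
    for pid in range(config.n_patients):
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 90))
        female = rng.random() < config.female_prob
        race = "White" if rng.random() < config.race_majority_prob else "Other"
        ethnicity = "Hispanic" if rng.random() < config.hispanic_prob else "Non-Hispanic"
        height = float(np.clip(rng.normal(config.height_mean, config.height_sd), 1.4, 2.1))
        bmi = float(max(rng.normal(config.bmi_mean, config.bmi_sd), config.bmi_min))
        weight0 = bmi * height**2
        entry = entry0 + pd.Timedelta(days=int(rng.integers(config.entry_span_days)))
        conds = {c: rng.random() < p for c, p in config.condition_prevalence.items()}
        any_cond = float(any(conds.values()))

        # qualifying prior visits for the eligibility rule
        prior_days = [-400.0, -20.0]
        n_vis = rng.poisson(config.visit_rate * T / 365.0)
        days = np.unique(np.concatenate([[0.0], np.round(rng.uniform(1, T, n_vis))]))

        events = []
        for name, model in config.exposure_uptake.items():
            events.extend(_uptake_events(name, model, bmi, any_cond, T, rng))
        edf = pd.DataFrame(events, columns=["kind", "day", "end_day", "drug"])
        timeline = build_exposure_segments(edf, (0.0, T))

        baseline = {"age_c": (age - 50.0) / 10.0, "female": float(female), "bmi_c": (bmi - 35.0) / 5.0}
        segs = []
        for dt, vec in timeline.segments_between(0.0, T):
            zdict = dict(zip(timeline.columns, vec))
            for k, v in baseline.items():
                if k in structure.covariates:
                    zdict[k] = v
            segs.append((dt, build_intensity_matrix(params, zdict, structure)))
        path = simulate_ctmc_path(segs, init_state=3, rng=rng)
        wts = emit_weights(path, weight0, days, rng)

        pat_rows.append(
            dict(
                patient_id=pid,
                age=age,
                sex="F" if female else "M",
                race=race,
                ethnicity=ethnicity,
                height_m=height,
                entry_date=entry.date().isoformat(),
                **{k: int(v) for k, v in conds.items()},
            )
        )
        for d in prior_days + list(days):
            visit_rows.append(dict(patient_id=pid, date=(entry + pd.Timedelta(days=d)).date().isoformat()))
        for d, w in zip(days, np.atleast_1d(wts)):
            weight_rows.append(
                dict(patient_id=pid, date=(entry + pd.Timedelta(days=d)).date().isoformat(), weight_kg=round(float(w), 2))
            )
        for ev in events:
            event_rows.append(
                dict(
                    patient_id=pid,
                    kind=ev["kind"],
                    date=(entry + pd.Timedelta(days=ev["day"])).date().isoformat(),
                    end_date=(
                        (entry + pd.Timedelta(days=ev["end_day"])).date().isoformat()
                        if np.isfinite(ev["end_day"])
                        else ""
                    ),
                    drug=ev["drug"],
                )
            )
        for c, v in conds.items():
            if v:
                cond_rows.append(dict(patient_id=pid, condition=c, date=entry.date().isoformat()))

    return RawEHRBundle(
        patients=pd.DataFrame(pat_rows),
        visits=pd.DataFrame(visit_rows, columns=["patient_id", "date"]),
        weights=pd.DataFrame(weight_rows, columns=["patient_id", "date", "weight_kg"]),
        wmt_events=pd.DataFrame(event_rows, columns=["patient_id", "kind", "date", "end_date", "drug"]),
        conditions=pd.DataFrame(cond_rows, columns=["patient_id", "condition", "date"]),
    )
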