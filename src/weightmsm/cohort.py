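"""Cohort construction: eligibility, weight-state coding, exposure timelines, panels.

This module turns raw linked EHR-style tables into the analysis artifacts the
rest of the package consumes:

* a five-state **weight-status ladder** relative to baseline weight
  (>=10% loss, 5-10% loss, within +/-5%, 5-10% gain, >=10% gain);
* piecewise-constant **exposure timelines** for the weight-management
  treatments (WMT): nutrition counseling in the prior 90 days, meal-replacement
  (MR) program participation split into early/late phases, any anti-obesity
  medication (AOM, pooled with GLP1RA), and time-since-bariatric-surgery bins;
* yearly **cross-sections** (first weight per patient per calendar year);
* the **panel dataset** of irregularly observed weight states with baseline
  covariates, which the multistate model is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateLadder",
    "RawEHRBundle",
    "ExposureTimeline",
    "PatientPanel",
    "PanelDataset",
    "EXPOSURE_COLUMNS",
    "SURGERY_BIN_COLUMNS",
    "derive_weight_states",
    "build_exposure_segments",
    "combination_exposure_intervals",
    "apply_eligibility",
    "extract_cross_section",
    "compute_utilization",
    "build_panel",
]

DAY = pd.Timedelta(days=1)

#: Time-varying exposure components, in the order used for covariate vectors.
#: Surgery is a single monotone time-since-surgery bin, one-hot encoded.
EXPOSURE_COLUMNS = (
    "nutrition_90d",
    "mr_early_active",
    "mr_late_active",
    "aom_any",
    "surg_0_90",
    "surg_91_180",
    "surg_181_364",
    "surg_ge365",
)
SURGERY_BIN_COLUMNS = ("surg_0_90", "surg_91_180", "surg_181_364", "surg_ge365")

# MR program phases, days since first program visit (~months 1-6 and 6-24).
MR_EARLY_END = 184.0  # early phase: [0, 184) days since program start
MR_LATE_END = 731.0  # late phase: [184, 731)
EXPOSURE_WINDOW = 90.0  # "in the prior 90 days" recency window
SURGERY_BIN_BREAKS = (0.0, 91.0, 181.0, 365.0)  # bins 0-90 / 91-180 / 181-364 / >=365


@dataclass(frozen=True)
class StateLadder:
    """Five weight states defined by relative-weight cut points.

    ``thresholds`` are multiples of baseline weight: (0.90, 0.95, 1.05, 1.10).
    Loss cut points are inclusive on the loss side and gain cut points on the
    gain side, so "10% or greater loss" means w <= 0.90*b and "5% or greater
    gain" means w >= 1.05*b; the stable state is the open interval
    (0.95*b, 1.05*b).
    """

    thresholds: tuple[float, float, float, float] = (0.90, 0.95, 1.05, 1.10)
    labels: tuple[str, ...] = (
        ">=10% loss",
        "5-10% loss",
        "baseline +/-5%",
        "5-10% gain",
        ">=10% gain",
    )

    def __post_init__(self) -> None:
        if len(self.thresholds) != 4 or list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be 4 strictly increasing cut points")
        if len(self.labels) != 5:
            raise ValueError("exactly 5 state labels required")


DEFAULT_LADDER = StateLadder()


def derive_weight_states(
    weights, baseline_weight: float, ladder: StateLadder = DEFAULT_LADDER
) -> np.ndarray:
    """Map weights to states 1..5 relative to ``baseline_weight``.

    Boundary convention (loss-side inclusive / gain-side inclusive):
    w <= 0.90b -> 1;  0.90b < w <= 0.95b -> 2;  0.95b < w < 1.05b -> 3;
    1.05b <= w < 1.10b -> 4;  w >= 1.10b -> 5.
    """
    if baseline_weight <= 0:
        raise ValueError("baseline_weight must be positive")
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    r = w / baseline_weight
    t1, t2, t3, t4 = ladder.thresholds
    states = np.full(w.shape, 3, dtype=int)
    states[r <= t2] = 2
    states[r <= t1] = 1
    states[r >= t3] = 4
    states[r >= t4] = 5
    return states if np.ndim(weights) else int(states[0])


# ---------------------------------------------------------------------------
# Raw tables
# ---------------------------------------------------------------------------


@dataclass
class RawEHRBundle:
    """Linked raw tables consumed by the pipeline.

    patients:   patient_id, age, sex, race, ethnicity, height_m, entry_date
    visits:     patient_id, date                       (primary-care visits)
    weights:    patient_id, date, weight_kg
    wmt_events: patient_id, kind, date, end_date, drug (WMT event streams)
    conditions: patient_id, condition, date            (incl. censoring events)
    """

    patients: pd.DataFrame
    visits: pd.DataFrame
    weights: pd.DataFrame
    wmt_events: pd.DataFrame
    conditions: pd.DataFrame

    TABLES = ("patients", "visits", "weights", "wmt_events", "conditions")

    def __post_init__(self) -> None:
        for name in self.TABLES:
            df = getattr(self, name)
            if not isinstance(df, pd.DataFrame):
                raise TypeError(f"{name} must be a DataFrame")
        for name, col in (("visits", "date"), ("weights", "date"), ("conditions", "date")):
            df = getattr(self, name)
            if len(df) and col in df.columns:
                df[col] = pd.to_datetime(df[col])
        if len(self.wmt_events):
            self.wmt_events["date"] = pd.to_datetime(self.wmt_events["date"])
            if "end_date" in self.wmt_events.columns:
                self.wmt_events["end_date"] = pd.to_datetime(self.wmt_events["end_date"])
        if len(self.patients) and "entry_date" in self.patients.columns:
            self.patients["entry_date"] = pd.to_datetime(self.patients["entry_date"])

    def write_csv(self, outdir) -> None:
        """Write the five tables as CSV (ISO-8601 dates, weights in kg)."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self.TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)

    @classmethod
    def read_csv(cls, indir) -> "RawEHRBundle":
        import pathlib

        ind = pathlib.Path(indir)
        return cls(**{name: pd.read_csv(ind / f"{name}.csv") for name in cls.TABLES})


# ---------------------------------------------------------------------------
# Exposure timelines
# ---------------------------------------------------------------------------


@dataclass
class ExposureTimeline:
    """Piecewise-constant WMT exposure vector over follow-up (days).

    ``values[i]`` applies on ``[changepoints[i], changepoints[i+1])`` and the
    last row through the end of follow-up. Columns follow EXPOSURE_COLUMNS.
    """

    changepoints: np.ndarray
    values: np.ndarray
    columns: tuple[str, ...] = EXPOSURE_COLUMNS

    def __post_init__(self) -> None:
        self.changepoints = np.asarray(self.changepoints, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.changepoints[0] != 0.0:
            raise ValueError("timeline must start at day 0")
        if np.any(np.diff(self.changepoints) <= 0):
            raise ValueError("changepoints must be strictly increasing")
        if self.values.shape != (len(self.changepoints), len(self.columns)):
            raise ValueError("values must be (n_changepoints, n_components)")

    def value_at(self, t: float) -> np.ndarray:
        idx = int(np.searchsorted(self.changepoints, t, side="right") - 1)
        return self.values[max(idx, 0)]

    def segments_between(self, t0: float, t1: float) -> list[tuple[float, np.ndarray]]:
        """Split [t0, t1] at interior changepoints -> list of (duration, vector)."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        if t1 == t0:
            return [(0.0, self.value_at(t0))]
        cps = self.changepoints
        interior = cps[(cps > t0) & (cps < t1)]
        bounds = np.concatenate(([t0], interior, [t1]))
        return [
            (float(b - a), self.value_at(a)) for a, b in zip(bounds[:-1], bounds[1:])
        ]

    def zeroed(self, which: str | None = None) -> "ExposureTimeline":
        """Return a copy with one WMT (or all, if ``which`` is None) set to 0.

        ``which`` is one of 'nutrition', 'mr', 'aom', 'surgery' or a column
        name; zeroing MR or surgery clears all of its component columns.
        """
        groups = {
            "nutrition": ["nutrition_90d"],
            "mr": ["mr_early_active", "mr_late_active"],
            "aom": ["aom_any"],
            "surgery": list(SURGERY_BIN_COLUMNS),
        }
        vals = self.values.copy()
        if which is None:
            vals[:] = 0.0
        else:
            cols = groups.get(which, [which])
            for c in cols:
                if c not in self.columns:
                    raise KeyError(f"unknown exposure component {c!r}")
                vals[:, self.columns.index(c)] = 0.0
        out = ExposureTimeline(self.changepoints.copy(), vals, self.columns)
        return out.simplified()

    def simplified(self) -> "ExposureTimeline":
        """Drop changepoints where no component actually changes."""
        keep = [0]
        for i in range(1, len(self.changepoints)):
            if not np.array_equal(self.values[i], self.values[keep[-1]]):
                keep.append(i)
        return ExposureTimeline(
            self.changepoints[keep], self.values[keep], self.columns
        )

    @classmethod
    def constant(cls, vector=None, columns=EXPOSURE_COLUMNS) -> "ExposureTimeline":
        if vector is None:
            vector = np.zeros(len(columns))
        return cls(np.array([0.0]), np.asarray(vector, float)[None, :], tuple(columns))


def _recency_indicator(event_days: np.ndarray, window: float):
    """Indicator of 'an event occurred in the prior ``window`` days'.

    An event on day d makes the indicator 1 on [d, d + window): the event
    counts on the day it occurs and expires after the window elapses.
    """
    starts = np.asarray(event_days, dtype=float)

    def f(t: float) -> float:
        return float(np.any((starts <= t) & (t < starts + window)))

    breaks = np.concatenate([starts, starts + window])
    return f, breaks


def build_exposure_segments(
    events: pd.DataFrame, followup: tuple[float, float]
) -> ExposureTimeline:
    """Construct a patient's piecewise-constant exposure timeline.

    ``events`` holds one patient's WMT rows with columns ``kind`` (one of
    'nutrition_visit', 'mr_visit', 'mr_program_start', 'aom_order',
    'surgery'), ``day`` (days from baseline; for AOM the order start) and
    ``end_day`` (AOM order end, half-open). ``followup`` is (0, T).

    Component definitions (t in days from baseline):
      * nutrition_90d(t): a dietitian visit in the prior 90 days;
      * mr_early_active(t): an MR visit in the prior 90 days and
        t - program_start < 184 (program months ~1-6);
      * mr_late_active(t): an MR visit in the prior 90 days and
        184 <= t - program_start < 731 (program months ~6-24);
      * aom_any(t): any AOM/GLP1RA order interval [start, end) covers t;
      * surgery bins: one-hot in days since surgery, 0-90 / 91-180 /
        181-364 / >=365, monotone non-decreasing.
    """
    t_start, t_end = followup
    if t_start != 0:
        raise ValueError("follow-up must start at day 0")
    if t_end <= 0:
        raise ValueError("follow-up end must be positive")

    def rows(kind):
        if len(events) == 0:
            return np.array([])
        return events.loc[events["kind"] == kind, "day"].to_numpy(dtype=float)

    indicators: dict[str, object] = {}
    breaks: list[np.ndarray] = []

    nut_f, nut_b = _recency_indicator(rows("nutrition_visit"), EXPOSURE_WINDOW)
    indicators["nutrition_90d"] = nut_f
    breaks.append(nut_b)

    mr_days = rows("mr_visit")
    explicit_start = rows("mr_program_start")
    if len(explicit_start):
        mr_start = float(explicit_start.min())
        if len(mr_days) and mr_days.min() < mr_start:
            raise ValueError("MR visit precedes program start")
    else:
        mr_start = float(mr_days.min()) if len(mr_days) else np.inf
    recent_mr, mr_b = _recency_indicator(mr_days, EXPOSURE_WINDOW)
    indicators["mr_early_active"] = lambda t: recent_mr(t) * float(
        0 <= t - mr_start < MR_EARLY_END
    )
    indicators["mr_late_active"] = lambda t: recent_mr(t) * float(
        MR_EARLY_END <= t - mr_start < MR_LATE_END
    )
    breaks.append(mr_b)
    if np.isfinite(mr_start):
        breaks.append(np.array([mr_start + MR_EARLY_END, mr_start + MR_LATE_END]))

    if len(events):
        aom = events[events["kind"] == "aom_order"]
        aom_starts = aom["day"].to_numpy(dtype=float)
        aom_ends = aom["end_day"].to_numpy(dtype=float)
    else:
        aom_starts = aom_ends = np.array([])
    if np.any(aom_ends < aom_starts):
        raise ValueError("AOM order end precedes start")

    def aom_f(t: float) -> float:
        return float(np.any((aom_starts <= t) & (t < aom_ends)))

    indicators["aom_any"] = aom_f
    breaks.append(aom_starts)
    breaks.append(aom_ends)

    surg_days = rows("surgery")
    if len(surg_days) > 1:
        raise ValueError("at most one bariatric surgery per patient")
    surg = float(surg_days[0]) if len(surg_days) else np.inf
    bin_edges = [surg + b for b in SURGERY_BIN_BREAKS] + [np.inf]
    for j, col in enumerate(SURGERY_BIN_COLUMNS):
        lo, hi = bin_edges[j], bin_edges[j + 1]
        indicators[col] = (lambda lo, hi: lambda t: float(lo <= t < hi))(lo, hi)
    if np.isfinite(surg):
        breaks.append(surg + np.asarray(SURGERY_BIN_BREAKS))

    all_breaks = np.concatenate([np.array([0.0])] + breaks)
    all_breaks = np.unique(all_breaks[(all_breaks >= 0) & (all_breaks < t_end)])
    values = np.array(
        [[indicators[c](t) for c in EXPOSURE_COLUMNS] for t in all_breaks]
    )
    return ExposureTimeline(all_breaks, values).simplified()


def combination_exposure_intervals(
    events: pd.DataFrame, drugs: tuple[str, str]
) -> list[tuple[float, float]]:
    """Overlap intervals of two single-agent AOM order streams.

    Captures off-label combinations (phentermine+topiramate,
    bupropion+naltrexone) as the pairwise intersections of the two drugs'
    order intervals; empty intersections are dropped.
    """
    out = []
    aom = events[events["kind"] == "aom_order"] if len(events) else events
    a = aom[aom["drug"] == drugs[0]] if len(aom) else aom
    b = aom[aom["drug"] == drugs[1]] if len(aom) else aom
    for _, ra in a.iterrows():
        for _, rb in b.iterrows():
            lo = max(float(ra["day"]), float(rb["day"]))
            hi = min(float(ra["end_day"]), float(rb["end_day"]))
            if hi >= lo:
                out.append((lo, hi))
    return sorted(out)


# ---------------------------------------------------------------------------
# Eligibility and cross-sections
# ---------------------------------------------------------------------------

CENSORING_CONDITIONS = ("death", "pregnancy", "metastatic_cancer")
VISIT_GAP_DAYS = 358
VISIT_LOOKBACK_DAYS = 3 * 365
BMI_RANGE = (12.0, 100.0)


def apply_eligibility(
    raw: RawEHRBundle, index_window: tuple | None = None
) -> pd.DataFrame:
    """Apply cohort entry, truncation, and BMI-plausibility rules.

    Entry requires two or more primary-care visits at least 358 days apart
    within a 3-year lookback; the entry date is the earliest visit that
    completes such a pair. Follow-up is truncated at the first
    death/pregnancy/metastatic-cancer event. Patients need at least two BMI
    measurements in [12, 100] before truncation. Returns a DataFrame with
    patient_id, entry_date, censor_date (NaT when uncensored).
    """
    if raw.visits is None or len(raw.visits) == 0:
        raise ValueError("visits table is missing or empty")
    visits = raw.visits.sort_values(["patient_id", "date"])

    entries = {}
    for pid, grp in visits.groupby("patient_id"):
        dates = grp["date"].to_numpy()
        entry = None
        for j in range(1, len(dates)):
            gap_ok = dates[:j] <= dates[j] - VISIT_GAP_DAYS * DAY
            window_ok = dates[:j] >= dates[j] - VISIT_LOOKBACK_DAYS * DAY
            if np.any(gap_ok & window_ok):
                entry = dates[j]
                break
        if entry is not None:
            entries[pid] = entry
    elig = pd.DataFrame(
        {"patient_id": list(entries.keys()), "entry_date": list(entries.values())}
    )
    if index_window is not None:
        lo, hi = (pd.Timestamp(x) for x in index_window)
        elig = elig[elig["entry_date"] <= hi]
        elig.loc[elig["entry_date"] < lo, "entry_date"] = lo

    cens = raw.conditions[
        raw.conditions["condition"].isin(CENSORING_CONDITIONS)
    ] if len(raw.conditions) else raw.conditions
    if len(cens):
        first_cens = cens.groupby("patient_id")["date"].min().rename("censor_date")
        elig = elig.merge(first_cens, on="patient_id", how="left")
    else:
        elig["censor_date"] = pd.NaT

    heights = raw.patients.set_index("patient_id")["height_m"]
    w = raw.weights.merge(elig, on="patient_id")
    if len(w):
        w = w[w["censor_date"].isna() | (w["date"] <= w["censor_date"])]
        bmi = w["weight_kg"] / w["patient_id"].map(heights) ** 2
        ok = (bmi >= BMI_RANGE[0]) & (bmi <= BMI_RANGE[1])
        n_ok = w[ok].groupby("patient_id").size()
    else:
        n_ok = pd.Series(dtype=int)
    keep = n_ok[n_ok >= 2].index
    return elig[elig["patient_id"].isin(keep)].reset_index(drop=True)


def extract_cross_section(raw: RawEHRBundle, year: int) -> pd.DataFrame:
    """First weight per patient in a calendar year, with BMI and obesity flag."""
    w = raw.weights.copy()
    w = w[w["date"].dt.year == year]
    if len(w) == 0:
        return pd.DataFrame(
            columns=["patient_id", "year", "date", "weight_kg", "bmi", "obese"]
        )
    w = w.sort_values("date").groupby("patient_id", as_index=False).first()
    heights = raw.patients.set_index("patient_id")["height_m"]
    w["bmi"] = w["weight_kg"] / w["patient_id"].map(heights) ** 2
    w["obese"] = (w["bmi"] >= 30.0).astype(int)
    w.insert(1, "year", year)
    return w


def compute_utilization(
    raw: RawEHRBundle,
    cross_section: pd.DataFrame,
    horizon: int = 364,
) -> pd.DataFrame:
    """Prospective 1-year WMT utilization among patients with obesity.

    Restricted to cross-section patients with obesity and at least
    ``horizon`` days of observed follow-up both before and after the index
    weight (bounded by first/last visit or weight and any truncation).
    Patients with bariatric surgery before index are excluded from the
    surgery denominator. "any_wmt" pools nutrition, MR, weight-management
    medications and surgery but not GLP1RA, which is reported separately.
    """
    cs = cross_section[cross_section["obese"] == 1].copy()
    frames = [
        t[["patient_id", "date"]] for t in (raw.visits, raw.weights) if len(t)
    ]
    obs = pd.concat(frames) if frames else raw.weights[["patient_id", "date"]]
    span = obs.groupby("patient_id")["date"].agg(["min", "max"])
    cs = cs.join(span, on="patient_id")
    full = cs[
        (cs["date"] - cs["min"] >= horizon * DAY)
        & (cs["max"] - cs["date"] >= horizon * DAY)
    ]

    ev = raw.wmt_events
    rows = []
    year = int(cs["year"].iloc[0]) if len(cs) else None

    def used(kinds, drugs=None, exclude_drugs=None):
        if len(ev) == 0 or len(full) == 0:
            return pd.Series(False, index=full["patient_id"])
        e = ev[ev["kind"].isin(kinds)]
        if drugs is not None:
            e = e[e["drug"].isin(drugs)]
        if exclude_drugs is not None:
            e = e[~e["drug"].isin(exclude_drugs)]
        m = e.merge(full[["patient_id", "date"]], on="patient_id", suffixes=("", "_idx"))
        hit = m[(m["date"] > m["date_idx"]) & (m["date"] <= m["date_idx"] + horizon * DAY)]
        flags = full["patient_id"].isin(hit["patient_id"].unique())
        flags.index = full["patient_id"].to_numpy()
        return flags

    nut = used(["nutrition_visit"])
    mr = used(["mr_visit"])
    med = used(["aom_order"], exclude_drugs=["glp1ra"])
    glp = used(["aom_order"], drugs=["glp1ra"])

    # surgery denominator: exclude prior-bariatric patients
    if len(ev):
        prior = ev[ev["kind"] == "surgery"].merge(
            full[["patient_id", "date"]], on="patient_id", suffixes=("", "_idx")
        )
        prior_ids = prior.loc[prior["date"] <= prior["date_idx"], "patient_id"].unique()
    else:
        prior_ids = []
    surg_denom = full[~full["patient_id"].isin(prior_ids)]
    surg = used(["surgery"]).reindex(surg_denom["patient_id"].to_numpy(), fill_value=False)

    any_wmt = nut | mr | med | used(["surgery"])

    for name, flags, denom in [
        ("nutrition", nut, len(full)),
        ("meal_replacement", mr, len(full)),
        ("weight_management_medications", med, len(full)),
        ("glp1ra", glp, len(full)),
        ("bariatric_surgery", surg, len(surg_denom)),
        ("any_wmt", any_wmt, len(full)),
    ]:
        n_used = int(flags.sum()) if denom else 0
        rows.append(
            {
                "year": year,
                "wmt": name,
                "n": denom,
                "n_used": n_used,
                "pct": 100.0 * n_used / denom if denom else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Panel dataset
# ---------------------------------------------------------------------------


@dataclass
class PatientPanel:
    """One patient's panel: observation days, observed states, covariates."""

    patient_id: object
    times: np.ndarray  # days from baseline, times[0] == 0
    states: np.ndarray  # 1..5, states[0] == 3 by construction
    baseline: dict  # baseline covariates by name
    exposure: ExposureTimeline

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")
        if len(self.times) and self.times[0] != 0:
            raise ValueError("panel must start at day 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any((self.states < 1) | (self.states > 5)):
            raise ValueError("states must be in 1..5")


@dataclass
class PanelDataset:
    """Collection of patient panels sharing a covariate vocabulary."""

    patients: list
    baseline_covariates: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_transitions_observed(self) -> int:
        return int(
            sum(np.sum(np.diff(p.states) != 0) for p in self.patients)
        )


def build_panel(
    raw: RawEHRBundle,
    eligibility: pd.DataFrame | None = None,
    baseline_covariates: tuple[str, ...] = ("age", "female"),
    require_obesity: bool = True,
    min_observations: int = 2,
    ladder: StateLadder = DEFAULT_LADDER,
) -> PanelDataset:
    """Assemble the trajectory panel from raw tables.

    The trajectory baseline is each patient's first qualifying weight (with
    BMI >= 30 when ``require_obesity``); subsequent weights at visit dates
    become observed states on the ladder; WMT events (re-expressed in days
    from baseline) become the exposure timeline; follow-up is truncated at
    censoring events.
    """
    if eligibility is None:
        eligibility = apply_eligibility(raw)
    heights = raw.patients.set_index("patient_id")["height_m"]
    pats = raw.patients.set_index("patient_id")
    out = []
    for _, row in eligibility.iterrows():
        pid = row["patient_id"]
        w = raw.weights[raw.weights["patient_id"] == pid].sort_values("date")
        w = w[w["date"] >= row["entry_date"]]
        if pd.notna(row.get("censor_date")):
            w = w[w["date"] <= row["censor_date"]]
        if len(w) < min_observations:
            continue
        w = w.groupby("date", as_index=False).first()  # first weight of the day
        bmi0 = w["weight_kg"].iloc[0] / heights[pid] ** 2
        if require_obesity and bmi0 < 30.0:
            continue
        b_date = w["date"].iloc[0]
        b_weight = float(w["weight_kg"].iloc[0])
        days = ((w["date"] - b_date) / DAY).to_numpy(dtype=float)
        states = derive_weight_states(w["weight_kg"].to_numpy(), b_weight, ladder)
        t_end = max(float(days[-1]), 1.0)
        if pd.notna(row.get("censor_date")):
            t_end = min(t_end, float((row["censor_date"] - b_date) / DAY))
        ev = raw.wmt_events[raw.wmt_events["patient_id"] == pid].copy()
        if len(ev):
            ev["day"] = ((ev["date"] - b_date) / DAY).astype(float)
            ev["end_day"] = (
                ((ev["end_date"] - b_date) / DAY).astype(float)
                if "end_date" in ev
                else np.nan
            )
            ev = ev[(ev["day"] < t_end) & ((ev["kind"] != "aom_order") | (ev["end_day"] > 0))]
            ev = ev[ev["day"] >= 0]  # prospective exposure only
        timeline = build_exposure_segments(ev, (0.0, t_end))
        prow = pats.loc[pid]
        base = {"age": float(prow["age"]), "female": float(prow["sex"] == "F")}
        base["bmi"] = float(bmi0)
        for k in baseline_covariates:
            if k not in base and k in prow.index:
                base[k] = float(prow[k])
        out.append(PatientPanel(pid, days, states, base, timeline))
    return PanelDataset(out, baseline_covariates)
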