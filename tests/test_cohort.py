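"""Cohort construction: state coding, exposure windows, eligibility, panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weightmsm.cohort import (
    EXPOSURE_COLUMNS,
    ExposureTimeline,
    apply_eligibility,
    build_exposure_segments,
    build_panel,
    combination_exposure_intervals,
    compute_utilization,
    derive_weight_states,
    extract_cross_section,
)
from weightmsm.synthetic_ehr import SimConfig, UptakeModel, simulate_population

from conftest import make_raw_bundle


class TestWeightStates:
    @pytest.mark.parametrize(
        "weight,expected",
        [
            (89.9, 1),
            (90.0, 1),  # 10% loss boundary belongs to the deeper-loss state
            (90.1, 2),
            (94.9, 2),
            (95.0, 2),  # 5% loss boundary is loss-side inclusive
            (95.1, 3),
            (104.9, 3),
            (105.0, 4),  # 5% gain boundary is gain-side inclusive
            (109.9, 4),
            (110.0, 5),
        ],
    )
    def test_boundary_conventions(self, weight, expected):
        assert derive_weight_states(weight, 100.0) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            derive_weight_states(-1.0, 100.0)
        with pytest.raises(ValueError):
            derive_weight_states(80.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        w=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
        b=st.floats(min_value=0.5, max_value=500.0, allow_nan=False),
    )
    def test_partition_property(self, w, b):
        """Every positive weight maps to exactly one state in 1..5."""
        s = derive_weight_states(w, b)
        assert s in {1, 2, 3, 4, 5}
        vec = derive_weight_states(np.array([w]), b)
        assert vec.shape == (1,) and vec[0] == s


class TestExposureTimeline:
    def test_single_nutrition_visit_window(self):
        ev = pd.DataFrame([dict(kind="nutrition_visit", day=10.0, end_day=np.nan, drug="")])
        tl = build_exposure_segments(ev, (0.0, 400.0))
        j = tl.columns.index("nutrition_90d")
        assert tl.value_at(9.9)[j] == 0
        assert tl.value_at(10.0)[j] == 1  # the visit counts on its own day
        assert tl.value_at(99.9)[j] == 1
        assert tl.value_at(100.0)[j] == 0

    def test_surgery_bins_advance(self):
        ev = pd.DataFrame([dict(kind="surgery", day=100.0, end_day=np.nan, drug="")])
        tl = build_exposure_segments(ev, (0.0, 600.0))

        def active_bin(t):
            v = tl.value_at(t)
            on = [c for c in tl.columns if c.startswith("surg") and v[tl.columns.index(c)]]
            return on

        assert active_bin(50.0) == []
        assert active_bin(150.0) == ["surg_0_90"]
        assert active_bin(300.0) == ["surg_181_364"]
        assert active_bin(500.0) == ["surg_ge365"]
        # the bin sequence is monotone non-decreasing in time
        order = {c: i for i, c in enumerate(("surg_0_90", "surg_91_180", "surg_181_364", "surg_ge365"))}
        seq = [order[b[0]] for t in np.linspace(101, 599, 200) for b in [active_bin(t)] if b]
        assert seq == sorted(seq)

    def test_combination_overlap(self):
        ev = pd.DataFrame(
            [
                dict(kind="aom_order", day=0.0, end_day=60.0, drug="phentermine"),
                dict(kind="aom_order", day=30.0, end_day=90.0, drug="topiramate"),
            ]
        )
        assert combination_exposure_intervals(ev, ("phentermine", "topiramate")) == [(30.0, 60.0)]
        tl = build_exposure_segments(ev, (0.0, 200.0))
        j = tl.columns.index("aom_any")
        assert tl.value_at(45.0)[j] == 1
        assert tl.value_at(89.0)[j] == 1
        assert tl.value_at(95.0)[j] == 0

    def test_mr_phases_and_program_start_error(self):
        ev = pd.DataFrame(
            [dict(kind="mr_visit", day=d, end_day=np.nan, drug="") for d in np.arange(0, 400, 30.0)]
        )
        tl = build_exposure_segments(ev, (0.0, 800.0))
        e = tl.columns.index("mr_early_active")
        l = tl.columns.index("mr_late_active")
        assert tl.value_at(100.0)[e] == 1 and tl.value_at(100.0)[l] == 0
        assert tl.value_at(300.0)[e] == 0 and tl.value_at(300.0)[l] == 1
        bad = pd.DataFrame(
            [
                dict(kind="mr_program_start", day=50.0, end_day=np.nan, drug=""),
                dict(kind="mr_visit", day=10.0, end_day=np.nan, drug=""),
            ]
        )
        with pytest.raises(ValueError, match="program start"):
            build_exposure_segments(bad, (0.0, 100.0))

    def test_piecewise_constant_between_changepoints(self):
        ev = pd.DataFrame(
            [
                dict(kind="nutrition_visit", day=20.0, end_day=np.nan, drug=""),
                dict(kind="aom_order", day=50.0, end_day=200.0, drug="orlistat"),
                dict(kind="surgery", day=300.0, end_day=np.nan, drug=""),
            ]
        )
        tl = build_exposure_segments(ev, (0.0, 700.0))
        assert np.isfinite(tl.changepoints).all() and len(tl.changepoints) < 20
        cps = np.concatenate([tl.changepoints, [700.0]])
        for a, b in zip(cps[:-1], cps[1:]):
            grid = np.linspace(a, b - 1e-9, 25)
            vals = np.array([tl.value_at(t) for t in grid])
            assert (vals == vals[0]).all()

    def test_zeroed_groups(self):
        ev = pd.DataFrame(
            [
                dict(kind="nutrition_visit", day=5.0, end_day=np.nan, drug=""),
                dict(kind="aom_order", day=0.0, end_day=300.0, drug="glp1ra"),
            ]
        )
        tl = build_exposure_segments(ev, (0.0, 400.0))
        assert np.all(tl.zeroed(None).values == 0)
        z = tl.zeroed("aom")
        assert all(z.value_at(t)[z.columns.index("aom_any")] == 0 for t in (0, 100, 250))
        assert z.value_at(50.0)[z.columns.index("nutrition_90d")] == 1

    def test_segments_between_sums_to_interval(self):
        ev = pd.DataFrame([dict(kind="nutrition_visit", day=30.0, end_day=np.nan, drug="")])
        tl = build_exposure_segments(ev, (0.0, 200.0))
        segs = tl.segments_between(10.0, 150.0)
        assert np.isclose(sum(d for d, _ in segs), 140.0)
        assert len(segs) == 3  # split at day 30 (on) and day 120 (off)


def _two_weight_rows(pid, dates, weights):
    return pd.DataFrame(
        [dict(patient_id=pid, date=d, weight_kg=w) for d, w in zip(dates, weights)]
    )


class TestEligibility:
    def _base(self, visit_days, weights=None, conditions=None):
        patients = pd.DataFrame(
            [dict(patient_id=1, age=50, sex="F", race="White", ethnicity="Non-Hispanic", height_m=1.6)]
        )
        visits = pd.DataFrame([dict(patient_id=1, date=d) for d in visit_days])
        if weights is None:
            weights = _two_weight_rows(1, ["2020-01-01", "2020-06-01"], [90.0, 91.0])
        return make_raw_bundle(patients=patients, visits=visits, weights=weights, conditions=conditions)

    def test_visit_gap_rule_edge(self):
        ok = apply_eligibility(self._base(["2019-01-01", "2019-12-27"]))  # 360 days apart
        assert list(ok["patient_id"]) == [1]
        too_close = apply_eligibility(self._base(["2019-01-01", "2019-10-28"]))  # 300 days
        assert len(too_close) == 0

    def test_visit_pair_outside_lookback(self):
        # 4 years apart: no qualifying pair within the 3-year lookback
        out = apply_eligibility(self._base(["2015-01-01", "2019-01-01"]))
        assert len(out) == 0

    def test_bmi_plausibility_rule(self):
        # height 1.6 m: weight 30.4 kg -> BMI 11.9 (implausible); 89.6 -> 35.0
        weights = _two_weight_rows(1, ["2020-01-01", "2020-06-01"], [30.4, 89.6])
        out = apply_eligibility(self._base(["2019-01-01", "2019-12-30"], weights=weights))
        assert len(out) == 0

    def test_truncation_at_censoring_event(self):
        conditions = pd.DataFrame([dict(patient_id=1, condition="death", date="2020-03-01")])
        weights = _two_weight_rows(1, ["2020-01-01", "2020-06-01"], [90.0, 91.0])
        out = apply_eligibility(self._base(["2019-01-01", "2019-12-30"], weights=weights, conditions=conditions))
        # only one pre-censoring weight remains -> excluded
        assert len(out) == 0

    def test_missing_visits_table_errors(self):
        raw = make_raw_bundle()
        with pytest.raises(ValueError, match="visits"):
            apply_eligibility(raw)


class TestCrossSection:
    def _raw(self):
        patients = pd.DataFrame(
            [dict(patient_id=1, age=50, sex="F", race="White", ethnicity="Non-Hispanic", height_m=1.6)]
        )
        patients["height_m"] = 2.0
        weights = _two_weight_rows(1, ["2017-03-01", "2017-09-01"], [120.0, 140.0])
        return make_raw_bundle(patients=patients, weights=weights)

    def test_first_weight_of_year_used(self):
        cs = extract_cross_section(self._raw(), 2017)
        assert len(cs) == 1 and cs["weight_kg"].iloc[0] == 120.0
        assert cs["bmi"].iloc[0] == pytest.approx(30.0)
        assert cs["obese"].iloc[0] == 1  # BMI exactly 30 counts as obese

    def test_absent_year_is_empty(self):
        cs = extract_cross_section(self._raw(), 2019)
        assert len(cs) == 0


class TestUtilization:
    def test_zero_uptake_gives_zero_rates(self):
        uptake = {k: UptakeModel(prob=0.0) for k in ("nutrition", "mr", "aom", "surgery")}
        raw = simulate_population(SimConfig(n_patients=60, exposure_uptake=uptake, seed=1))
        cs = extract_cross_section(raw, 2017)
        tab = compute_utilization(raw, cs)
        assert (tab["pct"] == 0).all()
        assert raw.wmt_events.empty

    def test_short_followup_excluded(self):
        patients = pd.DataFrame(
            [dict(patient_id=1, age=50, sex="F", race="White", ethnicity="Non-Hispanic", height_m=1.6)]
        )
        weights = _two_weight_rows(1, ["2017-01-01", "2017-07-01"], [90.0, 91.0])  # 181 days span
        raw = make_raw_bundle(patients=patients, weights=weights)
        tab = compute_utilization(raw, extract_cross_section(raw, 2017))
        assert (tab["n"] == 0).all()

    def test_binomial_recovery_of_uptake(self):
        """~5% configured nutrition uptake is recovered within 3 binomial SEs."""
        uptake = {
            "nutrition": UptakeModel(prob=0.05, bmi_coef=0.0, cond_coef=0.0, start_window=(10.0, 300.0)),
            "mr": UptakeModel(prob=0.0),
            "aom": UptakeModel(prob=0.0),
            "surgery": UptakeModel(prob=0.0),
        }
        raw = simulate_population(
            SimConfig(n_patients=1500, exposure_uptake=uptake, seed=7, followup_days=900)
        )
        cs = extract_cross_section(raw, 2017)
        tab = compute_utilization(raw, cs).set_index("wmt")
        n = tab.loc["nutrition", "n"]
        assert n > 500
        se = 100 * np.sqrt(0.05 * 0.95 / n)
        assert abs(tab.loc["nutrition", "pct"] - 5.0) < 3 * se


class TestPanel:
    def test_panel_invariants(self, small_panel):
        assert len(small_panel) > 100
        for p in small_panel.patients:
            assert p.times[0] == 0.0 and p.states[0] == 3
            assert np.all(np.diff(p.times) > 0)
            assert set(np.unique(p.states)) <= {1, 2, 3, 4, 5}
            assert p.baseline["bmi"] >= 30.0

    def test_roundtrip_states_from_emitted_weights(self, small_raw, small_panel):
        """States in the panel equal the ladder coding of the stored weights."""
        heights = small_raw.patients.set_index("patient_id")["height_m"]
        for p in small_panel.patients[:20]:
            w = small_raw.weights[small_raw.weights["patient_id"] == p.patient_id]
            w = w.sort_values("date")["weight_kg"].to_numpy()
            states = derive_weight_states(w, w[0])
            assert np.array_equal(states, p.states)
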