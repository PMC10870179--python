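"""Intensity model, interval probabilities, panel likelihood, ML fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from weightmsm import msm
from weightmsm.cohort import ExposureTimeline, PanelDataset, PatientPanel
from weightmsm.msm import (
    MSMParams,
    TRANSITIONS,
    TransitionStructure,
    build_intensity_matrix,
    crude_initial_estimates,
    fit_msm,
    hazard_ratios,
    interval_probability,
    panel_log_likelihood,
)
from weightmsm.synthetic_ehr import SimConfig, UptakeModel, default_true_params, simulate_population
from weightmsm.cohort import apply_eligibility, build_panel


def simple_patient(times, states, exposure_vec=None, baseline=None):
    tl = ExposureTimeline.constant(exposure_vec)
    return PatientPanel("p", np.asarray(times, float), np.asarray(states), baseline or {}, tl)


class TestIntensityMatrix:
    def test_zero_beta_reproduces_baseline(self, truth):
        params, structure = truth
        p0 = MSMParams(params.log_q0, np.zeros_like(params.beta))
        z1 = {c: 1.0 for c in structure.covariates}
        Q0 = build_intensity_matrix(p0, {}, structure)
        Q1 = build_intensity_matrix(p0, z1, structure)
        assert np.allclose(Q0, Q1)
        for k, (r, s) in enumerate(TRANSITIONS):
            assert Q0[r - 1, s - 1] == pytest.approx(np.exp(params.log_q0[k]))

    def test_forced_arithmetic_hr_doubles_rate(self):
        st_ = TransitionStructure.full(("x",))
        params = MSMParams.zeros(st_, log_q0=np.log(np.full(8, 0.1)))
        params.beta[:, 0] = np.log(2.0)
        Q = build_intensity_matrix(params, {"x": 1.0}, st_)
        k = TRANSITIONS.index((3, 4))
        assert Q[2, 3] == pytest.approx(0.2)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_rows_sum_to_zero_exactly(self, seed):
        rng = np.random.default_rng(seed)
        st_ = TransitionStructure.full(("a", "b"))
        params = MSMParams(rng.normal(-6, 1, 8), rng.normal(0, 0.5, (8, 2)))
        Q = build_intensity_matrix(params, rng.normal(0, 1, 2), st_)
        scale = max(1.0, np.abs(Q).max())
        assert np.all(np.abs(Q.sum(axis=1)) <= 1e-14 * scale)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)

    def test_nonfinite_predictor_raises(self):
        st_ = TransitionStructure.full(("x",))
        params = MSMParams.zeros(st_)
        params.beta[:, 0] = 1.0
        with pytest.raises(FloatingPointError, match="transition"):
            build_intensity_matrix(params, {"x": np.inf}, st_)


class TestIntervalProbability:
    def test_zero_duration_is_identity(self, truth):
        params, structure = truth
        P = interval_probability(params, [({}, 0.0)], structure)
        assert np.array_equal(P, np.eye(5))

    def test_two_state_closed_form(self):
        """Birth-death submodel 3<->4 against the analytic 2-state solution."""
        lam, mu, t = 0.01, 0.005, 100.0
        st_ = TransitionStructure.full(())
        params = MSMParams.zeros(st_, log_q0=np.log(np.full(8, 1e-300)))
        params.log_q0[TRANSITIONS.index((3, 4))] = np.log(lam)
        params.log_q0[TRANSITIONS.index((4, 3))] = np.log(mu)
        P = interval_probability(params, [(np.zeros(0), t)], st_)
        p33 = mu / (lam + mu) + (lam / (lam + mu)) * np.exp(-(lam + mu) * t)
        assert abs(P[2, 2] - p33) < 1e-10
        assert abs(P[2, 3] - (1 - p33)) < 1e-10

    def test_row_stochastic(self, truth):
        params, structure = truth
        z = {c: 1.0 for c in structure.covariates if c != "mr_late_active"}
        P = interval_probability(params, [(z, 200.0), ({}, 164.0)], structure)
        assert np.all(P >= -1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_chapman_kolmogorov_split_invariance(self, truth):
        """Splitting an interval at an interior point leaves P unchanged."""
        params, structure = truth
        z = {"aom_any": 1.0}
        whole = interval_probability(params, [(z, 364.0)], structure)
        split = interval_probability(params, [(z, 130.0), (z, 234.0)], structure)
        assert np.allclose(whole, split, atol=1e-12)

    def test_semigroup_364_equals_182_squared(self, truth):
        params, structure = truth
        P364 = interval_probability(params, [({}, 364.0)], structure)
        P182 = interval_probability(params, [({}, 182.0)], structure)
        assert np.allclose(P364, P182 @ P182, atol=1e-12)

    def test_negative_duration_rejected(self, truth):
        params, structure = truth
        with pytest.raises(ValueError):
            interval_probability(params, [({}, -1.0)], structure)


class TestPanelLikelihood:
    def test_hand_computed_two_interval_patient(self, truth):
        params, structure = truth
        patient = simple_patient([0.0, 120.0, 300.0], [3, 2, 2])
        panel = PanelDataset([patient])
        ll = panel_log_likelihood(params, panel, structure)
        Q = build_intensity_matrix(params, {}, structure)
        expected = np.log(expm(Q * 120.0)[2, 1]) + np.log(expm(Q * 180.0)[1, 1])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_changepoint_splitting_matches_manual_product(self, truth):
        params, structure = truth
        vec = np.zeros(len(ExposureTimeline.constant().columns))
        j = list(ExposureTimeline.constant().columns).index("aom_any")
        vals = np.array([vec, vec.copy()])
        vals[1, j] = 1.0
        tl = ExposureTimeline(np.array([0.0, 100.0]), vals)
        patient = PatientPanel("p", [0.0, 250.0], [3, 2], {}, tl)
        ll = panel_log_likelihood(params, PanelDataset([patient]), structure)
        Q0 = build_intensity_matrix(params, {}, structure)
        Q1 = build_intensity_matrix(params, {"aom_any": 1.0}, structure)
        expected = np.log((expm(Q0 * 100.0) @ expm(Q1 * 150.0))[2, 1])
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_truth_beats_perturbations_on_simulated_data(self, truth, small_panel):
        params, structure = truth
        comp = msm.compile_panel(small_panel, structure)
        ll_true = panel_log_likelihood(params, comp, structure)
        rng = np.random.default_rng(12)
        theta = params.pack(structure)
        for _ in range(20):
            pert = MSMParams.unpack(theta + rng.normal(0, 0.4, len(theta)), structure)
            assert panel_log_likelihood(pert, comp, structure) <= ll_true + 1e-9

    def test_analytic_gradient_matches_numeric(self, truth, small_panel):
        params, structure = truth
        comp = msm.compile_panel(small_panel, structure)
        theta = params.pack(structure)
        _, g = msm._loglik_and_grad(theta, comp, structure)
        rng = np.random.default_rng(13)
        for j in rng.choice(len(theta), size=6, replace=False):
            h = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            num = (
                msm._loglik_and_grad(tp, comp, structure)[0]
                - msm._loglik_and_grad(tm, comp, structure)[0]
            ) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestCrudeInit:
    def test_no_movers_floors_all_rates(self):
        panel = PanelDataset([simple_patient([0, 100, 200], [3, 3, 3])])
        init = crude_initial_estimates(panel)
        assert np.allclose(np.exp(init.log_q0), 1e-6)

    def test_forced_arithmetic_single_transition(self):
        panel = PanelDataset([simple_patient([0.0, 100.0], [3, 4])])
        init = crude_initial_estimates(panel)
        k = TRANSITIONS.index((3, 4))
        assert np.exp(init.log_q0[k]) == pytest.approx(0.01)

    def test_within_order_of_magnitude_on_dense_panel(self, truth, small_panel):
        params, structure = truth
        init = crude_initial_estimates(small_panel, structure)
        # transitions out of the well-populated baseline state
        for pair in ((3, 2), (3, 4)):
            k = TRANSITIONS.index(pair)
            assert abs(init.log_q0[k] - params.log_q0[k]) < np.log(10)

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            crude_initial_estimates(PanelDataset([]))


@pytest.fixture(scope="module")
def rich_panel():
    """Panel with common exposures, so every coefficient is well identified."""
    uptake = {
        "nutrition": UptakeModel(prob=0.4, bmi_coef=0.0, cond_coef=0.0, start_window=(0.0, 200.0)),
        "mr": UptakeModel(prob=0.0),
        "aom": UptakeModel(prob=0.35, bmi_coef=0.0, cond_coef=0.0, start_window=(0.0, 200.0)),
        "surgery": UptakeModel(prob=0.0),
    }
    raw = simulate_population(SimConfig(n_patients=300, seed=21, exposure_uptake=uptake))
    return build_panel(raw, apply_eligibility(raw))


@pytest.fixture(scope="module")
def fitted(rich_panel):
    # exposure effects only on the well-populated central transitions; the
    # tail transitions (1<->2, 4<->5) are too rare under exposure in a small
    # panel for their coefficients to be identified
    covs = ("nutrition_90d", "aom_any")
    mask = np.zeros((8, 2), bool)
    for pair in ((2, 1), (3, 2), (4, 3), (2, 3), (3, 4)):
        mask[TRANSITIONS.index(pair)] = True
    st_ = TransitionStructure(covs, mask)
    return fit_msm(rich_panel, st_), st_


class TestFit:
    def test_convergence_and_diagnostics(self, fitted):
        fit, _ = fitted
        assert fit.converged
        assert fit.grad_norm < 1e-2
        assert np.isfinite(fit.loglik)
        assert fit.covariance is not None
        assert np.allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.diag(fit.covariance) > -1e-10)

    def test_jittered_inits_reach_same_optimum(self, rich_panel, fitted):
        fit, st_ = fitted
        rng = np.random.default_rng(14)
        comp = msm.compile_panel(rich_panel, st_)
        base = crude_initial_estimates(comp, st_)
        for i in range(5):
            theta = base.pack(st_) + rng.normal(0, 0.3, st_.n_free)
            refit = fit_msm(comp, st_, init=MSMParams.unpack(theta, st_), compute_covariance=False)
            assert refit.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_unidentified_covariate_warns(self, small_panel):
        st_ = TransitionStructure.full(("mr_late_active",))
        comp = msm.compile_panel(small_panel, st_)
        if np.ptp(comp.Z[:, 0]) == 0:
            with pytest.warns(UserWarning, match="no variation"):
                fit_msm(comp, st_, compute_covariance=False, maxiter=5)


class TestHazardRatios:
    def _fake_fit(self):
        st_ = TransitionStructure.full(("x",))
        params = MSMParams.zeros(st_, log_q0=np.full(8, -6.0))
        cov = np.diag(np.concatenate([np.full(8, 0.01), np.full(8, 0.01)]))
        return msm.MSMFit(params, st_, cov, -1.0, True, 0.0, 10, 5)

    def test_forced_arithmetic_ci(self):
        hr = hazard_ratios(self._fake_fit())
        row = hr[(hr["covariate"] == "x") & (hr["transition"] == "3->2")].iloc[0]
        assert row["hr"] == pytest.approx(1.0)
        assert row["lo"] == pytest.approx(np.exp(-1.96 * 0.1), rel=1e-6)
        assert row["hi"] == pytest.approx(np.exp(1.96 * 0.1), rel=1e-6)

    def test_masked_cells_reported_na(self):
        st_ = TransitionStructure.default(demographics=())
        params = MSMParams.zeros(st_, log_q0=np.full(8, -6.0))
        fit = msm.MSMFit(params, st_, np.eye(st_.n_free), -1.0, True, 0.0, 10, 5)
        hr = hazard_ratios(fit)
        cell = hr[(hr["transition"] == "3->2") & (hr["covariate"] == "mr_late_active")].iloc[0]
        assert not cell["estimated"] and np.isnan(cell["hr"])
        assert hr["transition"].nunique() == 8

    def test_loss_hr_increase_raises_loss_probability(self, truth):
        """Monotonicity: bigger loss-side AOM effect -> more 1-year loss."""
        params, structure = truth
        from weightmsm.prediction import state_probabilities

        base = state_probabilities((params, structure), {}, "aom").collapsed["loss"]
        boosted = params.copy()
        j = structure.covariates.index("aom_any")
        boosted.beta[:4, j] += 0.3
        up = state_probabilities((boosted, structure), {}, "aom").collapsed["loss"]
        assert up > base
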