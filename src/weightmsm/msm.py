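"""Panel-observed continuous-time multistate Markov model of weight status.

Five weight states relative to baseline (>=10% loss .. >=10% gain) form a
birth-death ladder: patients move only between adjacent states, at transition
intensities with a proportional (log-linear) covariate structure

    q_rs(z) = q0_rs * exp(beta_rs' z),

where z holds demographics and the time-varying WMT exposure indicators.
States are observed only at irregular clinic visits (panel observation), so
the likelihood of an observation pair (s_i at t_i, s_{i+1} at t_{i+1}) is an
entry of the interval transition-probability matrix

    P(t_i, t_{i+1}) = prod_j expm(Q(z_j) * dt_j),

the product running over the piecewise-constant exposure segments between the
two visits. Fitting is by maximum likelihood with an analytic gradient
(eigendecomposition form of the Frechet derivative of the matrix
exponential); the covariance is the inverse of the numerically differentiated
observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .cohort import EXPOSURE_COLUMNS, PanelDataset, PatientPanel

__all__ = [
    "N_STATES",
    "TRANSITIONS",
    "LOSS_TRANSITIONS",
    "GAIN_TRANSITIONS",
    "TransitionStructure",
    "MSMParams",
    "MSMFit",
    "build_intensity_matrix",
    "interval_probability",
    "panel_log_likelihood",
    "crude_initial_estimates",
    "fit_msm",
    "hazard_ratios",
]

N_STATES = 5

#: Loss-direction transitions (toward lower state index = more weight lost),
#: ordered as in the hazard-ratio table, then gain-direction transitions.
LOSS_TRANSITIONS = ((2, 1), (3, 2), (4, 3), (5, 4))
GAIN_TRANSITIONS = ((1, 2), (2, 3), (3, 4), (4, 5))
TRANSITIONS = LOSS_TRANSITIONS + GAIN_TRANSITIONS
N_TRANSITIONS = len(TRANSITIONS)

TRANSITION_LABELS = tuple(f"{r}->{s}" for r, s in TRANSITIONS)

#: Pooled "more than 90 days since surgery" indicator (union of the three
#: later time-since-surgery bins), available as a derived covariate, plus
#: coarser pooled levels for sparsely observed exposures: any
#: time-since-surgery bin and either MR program phase.
SURGERY_POOLED = "surg_gt90"
_POOLED_SOURCE = ("surg_91_180", "surg_181_364", "surg_ge365")
_DERIVED = {
    SURGERY_POOLED: _POOLED_SOURCE,
    "surg_any": ("surg_0_90",) + _POOLED_SOURCE,
    "mr_active": ("mr_early_active", "mr_late_active"),
}


@dataclass(frozen=True)
class TransitionStructure:
    """Allowed transitions plus per-transition covariate masks.

    ``covariates`` orders the covariate vector z; ``mask[k, c]`` says whether
    covariate c carries a coefficient on transition k (the 8 adjacent pairs,
    in TRANSITIONS order). Masked-out cells are fixed at log-HR 0 and are
    reported as not estimated.
    """

    covariates: tuple[str, ...]
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.shape != (N_TRANSITIONS, len(self.covariates)):
            raise ValueError("mask must be (8, n_covariates)")
        object.__setattr__(self, "mask", m)

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    @property
    def n_free(self) -> int:
        return N_TRANSITIONS + int(self.mask.sum())

    @classmethod
    def full(cls, covariates=()) -> "TransitionStructure":
        """Every listed covariate on every transition."""
        covariates = tuple(covariates)
        return cls(covariates, np.ones((N_TRANSITIONS, len(covariates)), bool))

    @classmethod
    def default(cls, demographics=("age_c", "female")) -> "TransitionStructure":
        """The production WMT structure with the usual masking pattern.

        Demographics, nutrition, MR-early and AOM enter all 8 transitions;
        MR-late and the granular time-since-surgery bins enter only the
        transitions out of the loss states (2->1, 1->2, 2->3); the pooled
        ">90 days since surgery" level enters only the transitions out of
        baseline (3->2 and 3->4).
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
            SURGERY_POOLED,
        )
        mask = np.zeros((N_TRANSITIONS, len(covariates)), bool)
        idx = {c: j for j, c in enumerate(covariates)}
        loss_state_rows = [TRANSITIONS.index(t) for t in ((2, 1), (1, 2), (2, 3))]
        baseline_rows = [TRANSITIONS.index(t) for t in ((3, 2), (3, 4))]
        for c in demographics + ("nutrition_90d", "mr_early_active", "aom_any"):
            mask[:, idx[c]] = True
        for k in loss_state_rows:
            for c in ("mr_late_active", "surg_0_90", "surg_91_180", "surg_181_364", "surg_ge365"):
                mask[k, idx[c]] = True
        for k in baseline_rows:
            mask[k, idx[SURGERY_POOLED]] = True
        return cls(covariates, mask)


@dataclass
class MSMParams:
    """Log baseline intensities (per day) and log hazard-ratio coefficients.

    ``log_q0`` has one entry per allowed transition (TRANSITIONS order);
    ``beta`` is dense (8, n_covariates) with zeros where the structure masks
    a covariate out.
    """

    log_q0: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.log_q0 = np.asarray(self.log_q0, dtype=float)
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if self.log_q0.shape != (N_TRANSITIONS,):
            raise ValueError("log_q0 must have 8 entries")
        if self.beta.shape[0] != N_TRANSITIONS:
            raise ValueError("beta must have 8 rows")
        if not (np.all(np.isfinite(self.log_q0)) and np.all(np.isfinite(self.beta))):
            raise ValueError("parameters must be finite")

    @classmethod
    def zeros(cls, structure: TransitionStructure, log_q0=None) -> "MSMParams":
        lq = np.full(N_TRANSITIONS, -8.0) if log_q0 is None else np.asarray(log_q0, float)
        return cls(lq, np.zeros((N_TRANSITIONS, structure.n_covariates)))

    def pack(self, structure: TransitionStructure) -> np.ndarray:
        return np.concatenate([self.log_q0, self.beta[structure.mask]])

    @classmethod
    def unpack(cls, theta: np.ndarray, structure: TransitionStructure) -> "MSMParams":
        theta = np.asarray(theta, dtype=float)
        beta = np.zeros((N_TRANSITIONS, structure.n_covariates))
        beta[structure.mask] = theta[N_TRANSITIONS:]
        return cls(theta[:N_TRANSITIONS].copy(), beta)

    def copy(self) -> "MSMParams":
        return MSMParams(self.log_q0.copy(), self.beta.copy())


def _expand_z(z, structure: TransitionStructure) -> np.ndarray:
    """Coerce a covariate vector or mapping to structure order.

    Accepts a dict of name -> value (missing exposure components default to
    0; the pooled surgery indicator is derived when absent) or an array
    already in structure order.
    """
    if isinstance(z, dict):
        zz = dict(z)
        for name, sources in _DERIVED.items():
            if name in structure.covariates and name not in zz:
                zz[name] = float(any(zz.get(c, 0.0) for c in sources))
        out = np.zeros(structure.n_covariates)
        for j, name in enumerate(structure.covariates):
            if name in zz:
                out[j] = float(zz[name])
            elif name in EXPOSURE_COLUMNS or name in _DERIVED:
                out[j] = 0.0
            else:
                raise KeyError(f"covariate {name!r} missing from profile")
        return out
    out = np.asarray(z, dtype=float)
    if out.shape != (structure.n_covariates,):
        raise ValueError("covariate vector length mismatch")
    return out


def _rates(params: MSMParams, Z: np.ndarray, structure: TransitionStructure) -> np.ndarray:
    """Transition rates q_rs(z) for a stack of covariate rows Z (n, p)."""
    eta = params.log_q0[None, :] + Z @ (params.beta * structure.mask).T
    if not np.all(np.isfinite(eta)):
        bad = np.argwhere(~np.isfinite(eta))
        k = int(bad[0, 1])
        raise FloatingPointError(
            f"non-finite linear predictor on transition {TRANSITION_LABELS[k]}"
        )
    return np.exp(eta)


def _q_stack(rates: np.ndarray) -> np.ndarray:
    """Assemble 5x5 generators from per-transition rates (n, 8)."""
    n = rates.shape[0]
    Q = np.zeros((n, N_STATES, N_STATES))
    for k, (r, s) in enumerate(TRANSITIONS):
        Q[:, r - 1, s - 1] = rates[:, k]
    d = Q.sum(axis=2)
    idx = np.arange(N_STATES)
    Q[:, idx, idx] = -d
    return Q


def build_intensity_matrix(params: MSMParams, z, structure: TransitionStructure) -> np.ndarray:
    """5x5 intensity matrix Q(z) with rows summing to zero.

    Off-diagonal allowed entries are q0_rs * exp(beta_rs' z) with masked
    covariates excluded; disallowed entries are 0.
    """
    zz = _expand_z(z, structure)
    return _q_stack(_rates(params, zz[None, :], structure))[0]


def interval_probability(params: MSMParams, segments, structure: TransitionStructure) -> np.ndarray:
    """Interval transition-probability matrix over exposure segments.

    ``segments`` is a list of (z, duration_days) in time order; the result is
    the time-ordered product of matrix exponentials expm(Q(z_j) * dt_j)
    (scaling-and-squaring Pade), exact under piecewise-constant intensities.
    """
    P = np.eye(N_STATES)
    for z, dt in segments:
        dt = float(dt)
        if dt < 0:
            raise ValueError("segment durations must be nonnegative")
        if dt == 0:
            continue
        Q = build_intensity_matrix(params, z, structure)
        P = P @ expm(Q * dt)
    return P


# ---------------------------------------------------------------------------
# Compiled panel and likelihood
# ---------------------------------------------------------------------------


@dataclass
class _CompiledPanel:
    """Flattened segment arrays for fast repeated likelihood evaluation."""

    Z: np.ndarray  # (U, p) unique covariate rows
    seg_z: np.ndarray  # (S,) index into Z
    seg_dt: np.ndarray  # (S,) durations, days
    seg_ptr: np.ndarray  # (I+1,) CSR pointers: interval i owns segs ptr[i]:ptr[i+1]
    from0: np.ndarray  # (I,) 0-based start states
    to0: np.ndarray  # (I,) 0-based end states
    n_patients: int
    n_transitions: int
    risk_time: np.ndarray  # (5,) time with intervals starting in each state
    trans_counts: np.ndarray  # (8,) observed adjacent interval transitions


def _patient_z(patient: PatientPanel, structure: TransitionStructure, exp_vec: np.ndarray) -> tuple:
    """Full covariate row for one exposure segment of one patient."""
    cols = patient.exposure.columns
    z = []
    for name in structure.covariates:
        if name in cols:
            z.append(float(exp_vec[cols.index(name)]))
        elif name in _DERIVED:
            z.append(
                float(
                    any(
                        exp_vec[cols.index(c)] for c in _DERIVED[name] if c in cols
                    )
                )
            )
        elif name in patient.baseline:
            z.append(float(patient.baseline[name]))
        else:
            raise KeyError(
                f"covariate {name!r} not found in exposures or baseline for "
                f"patient {patient.patient_id!r}"
            )
    return tuple(z)


def compile_panel(
    panel: PanelDataset,
    structure: TransitionStructure,
    covariate_timing: str = "changepoint",
) -> _CompiledPanel:
    """Flatten a panel into segment arrays.

    ``covariate_timing='changepoint'`` splits every observation interval at
    the patient's exposure changepoints (exact under the model);
    ``'interval-start'`` uses the exposure value at the interval's left
    endpoint for the whole interval (compatibility mode).
    """
    if covariate_timing not in ("changepoint", "interval-start"):
        raise ValueError("covariate_timing must be 'changepoint' or 'interval-start'")
    zmap: dict[tuple, int] = {}
    seg_z, seg_dt, ptr = [], [], [0]
    from0, to0 = [], []
    risk_time = np.zeros(N_STATES)
    trans_counts = np.zeros(N_TRANSITIONS)
    tindex = {t: k for k, t in enumerate(TRANSITIONS)}
    for p in panel.patients:
        for i in range(len(p.times) - 1):
            t0, t1 = p.times[i], p.times[i + 1]
            if covariate_timing == "changepoint":
                segs = p.exposure.segments_between(t0, t1)
            else:
                segs = [(t1 - t0, p.exposure.value_at(t0))]
            for dt, vec in segs:
                key = _patient_z(p, structure, vec)
                u = zmap.setdefault(key, len(zmap))
                seg_z.append(u)
                seg_dt.append(float(dt))
            ptr.append(len(seg_z))
            from0.append(p.states[i] - 1)
            to0.append(p.states[i + 1] - 1)
            risk_time[p.states[i] - 1] += t1 - t0
            pair = (int(p.states[i]), int(p.states[i + 1]))
            if pair in tindex:
                trans_counts[tindex[pair]] += 1
    if not from0:
        raise ValueError("panel contains no observation intervals")
    Z = np.array(list(zmap.keys()), dtype=float).reshape(len(zmap), structure.n_covariates)
    return _CompiledPanel(
        Z,
        np.asarray(seg_z),
        np.asarray(seg_dt),
        np.asarray(ptr),
        np.asarray(from0),
        np.asarray(to0),
        n_patients=len(panel.patients),
        n_transitions=int(trans_counts.sum()),
        risk_time=risk_time,
        trans_counts=trans_counts,
    )


_COND_LIMIT = 1e10
_TINY = 1e-300


def _eig_factors(Q: np.ndarray):
    lam, V = np.linalg.eig(Q)
    Vi = np.linalg.inv(V)
    cond = np.linalg.cond(V)
    return lam, V, Vi, cond


def _divided_difference(lam: np.ndarray, dt: np.ndarray) -> np.ndarray:
    """F[i,j] = (e^{li t} - e^{lj t}) / (li - lj), with the i==j limit t e^{li t}.

    lam: (S, 5) complex eigenvalues per segment; dt: (S,).
    """
    lt = lam * dt[:, None]
    E = np.exp(lt)
    dL = lam[:, :, None] - lam[:, None, :]
    num = E[:, :, None] - E[:, None, :]
    small = np.abs(dL) < 1e-9
    mid = 0.5 * (lt[:, :, None] + lt[:, None, :])
    limit = dt[:, None, None] * np.exp(mid)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(small, limit, num / np.where(small, 1.0, dL))
    return F, E


def _loglik_and_grad(theta: np.ndarray, comp: _CompiledPanel, structure: TransitionStructure):
    """Panel log-likelihood and analytic gradient via eigen-decomposition.

    Falls back to a matrix-exponential + complex-step path if any unique
    generator has a badly conditioned eigenvector matrix.
    """
    params = MSMParams.unpack(theta, structure)
    rates = _rates(params, comp.Z, structure)  # (U, 8)
    if not np.all(np.isfinite(rates)):
        raise FloatingPointError("transition rates overflowed")
    Qs = _q_stack(rates)  # (U, 5, 5)
    lam, V = np.linalg.eig(Qs)
    Vi = np.linalg.inv(V)
    conds = np.linalg.cond(V)
    if np.any(conds > _COND_LIMIT) or not np.all(np.isfinite(conds)):
        return _loglik_and_grad_expm(theta, comp, structure)

    lam_s = lam[comp.seg_z]  # (S, 5) complex
    V_s = V[comp.seg_z]
    Vi_s = Vi[comp.seg_z]
    F, E = _divided_difference(lam_s, comp.seg_dt)
    # P for every segment
    P = np.einsum("sij,sj,sjk->sik", V_s, E, Vi_s).real
    P = np.clip(P, 0.0, None)

    S = len(comp.seg_dt)
    a = np.empty((S, N_STATES), dtype=complex)  # prefix row in eigen basis
    b = np.empty((S, N_STATES), dtype=complex)  # suffix col in eigen basis
    w = np.empty(S)  # 1 / interval probability, per owning segment
    loglik = 0.0
    nI = len(comp.from0)
    ptr = comp.seg_ptr
    for i in range(nI):
        lo, hi = ptr[i], ptr[i + 1]
        f0, t0 = comp.from0[i], comp.to0[i]
        if hi - lo == 1:
            p = P[lo, f0, t0]
            a[lo] = V_s[lo, f0, :]
            b[lo] = Vi_s[lo, :, t0]
        else:
            # prefix rows
            u = np.zeros(N_STATES)
            u[f0] = 1.0
            for j in range(lo, hi):
                a[j] = u @ V_s[j]
                u = u @ P[j]
            p = u[t0]
            # suffix columns (backward)
            v = np.zeros(N_STATES)
            v[t0] = 1.0
            for j in range(hi - 1, lo - 1, -1):
                b[j] = Vi_s[j] @ v
                v = P[j] @ v
        p = max(p, _TINY)
        loglik += np.log(p)
        w[lo:hi] = 1.0 / p

    # A[s] = outer(a, b) * F ; g[s, k] = <A[s], G[u_s, k]>
    A = a[:, :, None] * F * b[:, None, :]
    # G[u, k] = Vi[u] B_k V[u], with B_k = E_{r k s k} - E_{r k r k}
    G = np.empty((len(comp.Z), N_TRANSITIONS, N_STATES, N_STATES), dtype=complex)
    for k, (r, s) in enumerate(TRANSITIONS):
        G[:, k] = Vi[:, :, r - 1][:, :, None] * (V[:, s - 1, :] - V[:, r - 1, :])[:, None, :]
    gRe = np.einsum("sij,skij->sk", A, G[comp.seg_z]).real  # (S, 8)

    with np.errstate(over="ignore", invalid="ignore"):
        T = w[:, None] * rates[comp.seg_z] * gRe  # (S, 8)
        grad_logq0 = T.sum(axis=0)
        grad_beta = T.T @ comp.Z[comp.seg_z]  # (8, p)
    grad = np.concatenate([grad_logq0, grad_beta[structure.mask]])
    return float(loglik), grad


def _loglik_value_expm(theta, comp: _CompiledPanel, structure: TransitionStructure):
    """Likelihood via batched scaling-and-squaring expm; complex-safe."""
    params_lq = theta[:N_TRANSITIONS]
    beta = np.zeros((N_TRANSITIONS, structure.n_covariates), dtype=theta.dtype)
    beta[structure.mask] = theta[N_TRANSITIONS:]
    eta = params_lq[None, :] + comp.Z @ (beta * structure.mask).T
    rates = np.exp(eta)
    n = rates.shape[0]
    Q = np.zeros((n, N_STATES, N_STATES), dtype=rates.dtype)
    for k, (r, s) in enumerate(TRANSITIONS):
        Q[:, r - 1, s - 1] = rates[:, k]
    idx = np.arange(N_STATES)
    Q[:, idx, idx] = -Q.sum(axis=2)[:, idx]
    P = expm(Q[comp.seg_z] * comp.seg_dt[:, None, None])
    loglik = 0.0 + 0.0j if np.iscomplexobj(P) else 0.0
    any_zero = False
    ptr = comp.seg_ptr
    for i in range(len(comp.from0)):
        lo, hi = ptr[i], ptr[i + 1]
        u = P[lo][comp.from0[i]]
        for j in range(lo + 1, hi):
            u = u @ P[j]
        p = u[comp.to0[i]]
        if np.real(p) <= 0:
            any_zero = True
            p = _TINY + 0 * p
        loglik += np.log(p)
    return loglik, any_zero


def _loglik_and_grad_expm(theta, comp, structure):
    """Fallback: Pade expm value plus complex-step gradient."""
    val, _ = _loglik_value_expm(theta.astype(float), comp, structure)
    h = 1e-200
    grad = np.empty(len(theta))
    for j in range(len(theta)):
        tc = theta.astype(complex)
        tc[j] += 1j * h
        gval, _ = _loglik_value_expm(tc, comp, structure)
        grad[j] = np.imag(gval) / h
    return float(np.real(val)), grad


def panel_log_likelihood(
    params: MSMParams,
    panel,
    structure: TransitionStructure,
    covariate_timing: str = "changepoint",
) -> float:
    """Interval-censored panel log-likelihood.

    Sum over patients and consecutive observation pairs of
    log P[s_i -> s_{i+1}] over the exposure segments between the visits.
    An impossible observation (zero probability) yields -inf.
    """
    comp = panel if isinstance(panel, _CompiledPanel) else compile_panel(
        panel, structure, covariate_timing
    )
    theta = params.pack(structure)
    val, any_zero = _loglik_value_expm(theta, comp, structure)
    return -np.inf if any_zero else float(np.real(val))


def crude_initial_estimates(panel, structure: TransitionStructure | None = None) -> MSMParams:
    """Initial values: observed interval transitions / time at risk, betas 0.

    Counts adjacent-state changes between consecutive observations as if
    they were direct transitions and divides by the total time spent in
    intervals starting from the origin state; rates are floored at 1e-6/day.
    """
    structure = structure or TransitionStructure.full(())
    comp = panel if isinstance(panel, _CompiledPanel) else compile_panel(
        panel, structure, "interval-start"
    )
    if len(comp.from0) == 0:
        raise ValueError("empty panel")
    q0 = np.empty(N_TRANSITIONS)
    for k, (r, _s) in enumerate(TRANSITIONS):
        t_risk = comp.risk_time[r - 1]
        q0[k] = comp.trans_counts[k] / t_risk if t_risk > 0 else 0.0
    q0 = np.maximum(q0, 1e-6)
    return MSMParams(np.log(q0), np.zeros((N_TRANSITIONS, structure.n_covariates)))


@dataclass
class MSMFit:
    """Fitted model: point estimates, covariance, and diagnostics."""

    params: MSMParams
    structure: TransitionStructure
    covariance: np.ndarray | None
    loglik: float
    converged: bool
    grad_norm: float
    n_patients: int
    n_transitions: int
    covariate_timing: str = "changepoint"

    @property
    def theta(self) -> np.ndarray:
        return self.params.pack(self.structure)

    def se(self) -> np.ndarray | None:
        if self.covariance is None:
            return None
        return np.sqrt(np.clip(np.diag(self.covariance), 0, None))


def _observed_information(theta, comp, structure, step=1e-5):
    """Negative Hessian of the log-likelihood by central differences of the
    analytic gradient."""
    n = len(theta)
    H = np.empty((n, n))
    for j in range(n):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _loglik_and_grad(tp, comp, structure)
        _, gm = _loglik_and_grad(tm, comp, structure)
        H[j] = (gp - gm) / (2 * h)
    H = 0.5 * (H + H.T)
    return -H


def _newton_polish(theta, comp, structure, objective, max_steps: int = 8):
    """Damped Newton refinement; returns (theta, last observed information)."""
    f, g = objective(theta)
    info = None
    for _ in range(max_steps):
        if np.max(np.abs(g)) < 1e-7:
            break
        try:
            info = _observed_information(theta, comp, structure)
            if not np.all(np.isfinite(info)):
                break
            step = np.linalg.solve(info, -g)  # g is the negative-loglik gradient
        except (np.linalg.LinAlgError, FloatingPointError):
            break
        if not np.all(np.isfinite(step)):
            break
        scale, improved = 1.0, False
        for _ls in range(12):
            f_new, g_new = objective(theta + scale * step)
            if f_new < f:
                theta, f, g = theta + scale * step, f_new, g_new
                improved = True
                break
            scale *= 0.5
        if not improved:
            break
    return theta, info


def fit_msm(
    panel,
    structure: TransitionStructure,
    init: MSMParams | None = None,
    covariate_timing: str = "changepoint",
    maxiter: int = 500,
    gtol: float = 1e-5,
    compute_covariance: bool = True,
) -> MSMFit:
    """Maximum-likelihood fit of the panel multistate model.

    Quasi-Newton (L-BFGS-B) maximization over (log q0, beta) with an
    analytic gradient; the covariance estimate is the inverse observed
    information at the optimum. Non-convergence returns a fit flagged
    ``converged=False`` rather than raising.
    """
    comp = panel if isinstance(panel, _CompiledPanel) else compile_panel(
        panel, structure, covariate_timing
    )
    # identifiability warning: masked covariate with no variation in Z
    for j, name in enumerate(structure.covariates):
        if structure.mask[:, j].any() and np.ptp(comp.Z[:, j]) == 0 and len(comp.Z) > 1:
            warnings.warn(
                f"covariate {name!r} has no variation across segments; "
                "its coefficients are weakly identified",
                stacklevel=2,
            )
    if init is None:
        init = crude_initial_estimates(comp, structure)
    theta0 = init.pack(structure)

    def objective(theta):
        try:
            ll, g = _loglik_and_grad(theta, comp, structure)
        except FloatingPointError:
            return 1e12, np.zeros_like(theta)
        if not (np.isfinite(ll) and np.all(np.isfinite(g))):
            # off the feasible region (overflowing rates); force a backtrack
            return 1e12, np.zeros_like(theta)
        return -ll, -g

    theta_hat = theta0
    res = None
    for _attempt in range(3):  # restarts reset L-BFGS curvature memory
        res = minimize(
            objective,
            theta_hat,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        theta_hat = res.x
        if np.max(np.abs(res.jac)) < 1e-3:
            break
    # Newton polish: flat ridges can stall limited-memory quasi-Newton short
    # of the optimum; a few damped Newton steps with the observed information
    # settle it to high precision
    theta_hat, _ = _newton_polish(theta_hat, comp, structure, objective)
    ll, grad = _loglik_and_grad(theta_hat, comp, structure)
    cov = None
    if compute_covariance:
        try:
            info = _observed_information(theta_hat, comp, structure)
            cov = np.linalg.inv(info)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < -1e-8):
                raise np.linalg.LinAlgError
        except (np.linalg.LinAlgError, FloatingPointError):
            warnings.warn("singular observed information; covariance unavailable", stacklevel=2)
            cov = None
    return MSMFit(
        params=MSMParams.unpack(theta_hat, structure),
        structure=structure,
        covariance=cov,
        loglik=float(ll),
        converged=bool(res.success or np.max(np.abs(grad)) < 1e-2),
        grad_norm=float(np.max(np.abs(grad))),
        n_patients=comp.n_patients,
        n_transitions=comp.n_transitions,
        covariate_timing=covariate_timing if not isinstance(panel, _CompiledPanel) else covariate_timing,
    )


def hazard_ratios(fit: MSMFit, z: float = 1.96) -> pd.DataFrame:
    """Tidy table of hazard ratios with Wald CIs per transition x covariate.

    HR = exp(beta_hat), CI = exp(beta_hat +/- 1.96 SE); cells masked out of
    the structure are reported with ``estimated=False`` and NaN values.
    """
    st = fit.structure
    se = fit.se()
    free_idx = np.full((N_TRANSITIONS, st.n_covariates), -1, dtype=int)
    free_idx[st.mask] = N_TRANSITIONS + np.arange(int(st.mask.sum()))
    rows = []
    for k, label in enumerate(TRANSITION_LABELS):
        direction = "loss" if k < 4 else "gain"
        for j, name in enumerate(st.covariates):
            if st.mask[k, j]:
                b = fit.params.beta[k, j]
                s = se[free_idx[k, j]] if se is not None else np.nan
                rows.append(
                    dict(
                        transition=label,
                        direction=direction,
                        covariate=name,
                        hr=np.exp(b),
                        lo=np.exp(b - z * s),
                        hi=np.exp(b + z * s),
                        estimated=True,
                    )
                )
            else:
                rows.append(
                    dict(
                        transition=label,
                        direction=direction,
                        covariate=name,
                        hr=np.nan,
                        lo=np.nan,
                        hi=np.nan,
                        estimated=False,
                    )
                )
    return pd.DataFrame(rows)
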