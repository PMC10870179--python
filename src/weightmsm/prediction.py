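"""One-year state probabilities for covariate/exposure profiles.

Summaries of the fitted multistate model: the 364-day state distribution
from a start state under an assumed (idealized, uninterrupted) WMT exposure
schedule, collapsed loss/stable/gain probabilities, and percentile CIs from
multivariate-normal simulation of the parameter estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .msm import MSMFit, MSMParams, TransitionStructure, interval_probability

__all__ = [
    "HORIZON_DAYS",
    "StateProbVector",
    "idealized_segments",
    "state_probabilities",
    "collapse_states",
    "simulate_parameter_uncertainty",
]

HORIZON_DAYS = 364.0


@dataclass
class StateProbVector:
    """Five-state occupancy probabilities at a horizon for one profile."""

    probs: np.ndarray
    horizon: float
    profile: dict = field(default_factory=dict)
    start_state: int = 3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (5,):
            raise ValueError("need exactly 5 probabilities")
        if np.any(self.probs < -1e-10) or abs(self.probs.sum() - 1.0) > 1e-8:
            raise ValueError("probabilities must be nonnegative and sum to 1")

    @property
    def collapsed(self) -> dict:
        return collapse_states(self)


def collapse_states(v) -> dict:
    """Collapse 5 state probabilities to loss / stable / gain summaries.

    loss = p1 + p2 (>=5% loss, inclusive of >=10%), stable = p3,
    gain = p4 + p5; also reports the >=10% tails p1 and p5.
    """
    p = v.probs if isinstance(v, StateProbVector) else np.asarray(v, dtype=float)
    return {
        "loss": float(p[0] + p[1]),
        "stable": float(p[2]),
        "gain": float(p[3] + p[4]),
        "loss10": float(p[0]),
        "gain10": float(p[4]),
    }


def idealized_segments(
    wmt: str | None, horizon: float = HORIZON_DAYS, mr_mode: str = "phased"
) -> list[tuple[dict, float]]:
    """Exposure segments for year-long, uninterrupted use of one WMT.

    Returns (exposure dict, duration) pairs covering [0, horizon]:

    * ``None``/"none": no WMT for the whole horizon;
    * "nutrition": counseling active throughout;
    * "mr": program phases advance (early for days 0-183, then late); with
      ``mr_mode='early-throughout'`` the early phase is held for the full
      horizon instead;
    * "aom": medication exposure throughout;
    * "surgery": surgery at day 0, the time-since-surgery bin advancing
      deterministically 0-90 / 91-180 / 181-364 (the >=365 bin is not
      reached within a 364-day horizon).
    """
    if wmt in (None, "none"):
        return [({}, horizon)]
    if wmt == "nutrition":
        return [({"nutrition_90d": 1.0}, horizon)]
    if wmt == "mr":
        if mr_mode == "early-throughout":
            return [({"mr_early_active": 1.0}, horizon)]
        if mr_mode != "phased":
            raise ValueError("mr_mode must be 'phased' or 'early-throughout'")
        early = min(184.0, horizon)
        segs = [({"mr_early_active": 1.0}, early)]
        if horizon > early:
            segs.append(({"mr_late_active": 1.0}, horizon - early))
        return segs
    if wmt == "aom":
        return [({"aom_any": 1.0}, horizon)]
    if wmt == "surgery":
        bins = [("surg_0_90", 91.0), ("surg_91_180", 90.0), ("surg_181_364", 184.0), ("surg_ge365", np.inf)]
        segs, t = [], 0.0
        for name, dur in bins:
            if t >= horizon:
                break
            d = min(dur, horizon - t)
            segs.append(({name: 1.0}, d))
            t += d
        return segs
    raise ValueError(f"unknown WMT {wmt!r}")


def _resolve(fit) -> tuple[MSMParams, TransitionStructure]:
    if isinstance(fit, MSMFit):
        return fit.params, fit.structure
    params, structure = fit
    return params, structure


def state_probabilities(
    fit,
    profile: dict | None = None,
    exposure=None,
    horizon: float = HORIZON_DAYS,
    start_state: int = 3,
    mr_mode: str = "phased",
) -> StateProbVector:
    """State distribution at ``horizon`` days from ``start_state``.

    ``profile`` carries the baseline covariates (e.g. the reference patient:
    female, age 50, BMI 35, one prior-year visit, encoded however the
    structure's covariates expect); ``exposure`` is a WMT name handled by
    :func:`idealized_segments`, or an explicit list of (exposure dict,
    duration) segments. The result is the ``start_state`` row of the
    product of matrix exponentials over the segments.
    """
    params, structure = _resolve(fit)
    if not 1 <= start_state <= 5:
        raise ValueError("start_state must be in 1..5")
    profile = dict(profile or {})
    if exposure is None or isinstance(exposure, str):
        segments = idealized_segments(exposure, horizon, mr_mode)
    else:
        segments = exposure
    merged = [({**profile, **dict(seg)}, dur) for seg, dur in segments]
    P = interval_probability(params, merged, structure)
    return StateProbVector(
        P[start_state - 1],
        horizon=horizon,
        profile={"baseline": profile, "exposure": exposure},
        start_state=start_state,
    )


def _nearest_psd(cov: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (cov + cov.T))
    if np.min(vals) >= 0:
        return cov
    warnings.warn("covariance not PSD; clipping negative eigenvalues", stacklevel=3)
    return (vecs * np.clip(vals, 0, None)) @ vecs.T


def simulate_parameter_uncertainty(
    fit: MSMFit,
    functional,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Percentile CI of ``functional(params)`` under MVN parameter draws.

    Draws B parameter vectors from N(theta_hat, Sigma_hat), evaluates the
    functional (any scalar or vector derived from the parameters) on each,
    and returns the alpha/2 and 1-alpha/2 percentiles. Deterministic given
    ``seed``.
    """
    if fit.covariance is None:
        raise ValueError("fit has no covariance estimate")
    rng = np.random.default_rng(seed)
    cov = _nearest_psd(np.asarray(fit.covariance))
    theta = fit.theta
    draws_theta = rng.multivariate_normal(theta, cov, size=B, method="svd")
    vals = np.array(
        [np.atleast_1d(functional(MSMParams.unpack(t, fit.structure))) for t in draws_theta]
    )
    lo = np.percentile(vals, 100 * alpha / 2, axis=0)
    hi = np.percentile(vals, 100 * (1 - alpha / 2), axis=0)
    point = np.atleast_1d(functional(fit.params))
    squeeze = point.shape == (1,)
    return {
        "point": float(point[0]) if squeeze else point,
        "lo": float(lo[0]) if squeeze else lo,
        "hi": float(hi[0]) if squeeze else hi,
        "draws": vals[:, 0] if squeeze else vals,
    }
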