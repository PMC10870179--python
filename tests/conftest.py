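import numpy as np
import pandas as pd
import pytest

from weightmsm import msm
from weightmsm.cohort import apply_eligibility, build_panel
from weightmsm.synthetic_ehr import SimConfig, default_true_params, simulate_population


@pytest.fixture(scope="session")
def truth():
    """Ground-truth parameters on the exposure-only structure."""
    return default_true_params()


@pytest.fixture(scope="session")
def small_raw():
    """A small synthetic cohort under default study conditions."""
    return simulate_population(SimConfig(n_patients=250, seed=42))


@pytest.fixture(scope="session")
def small_panel(small_raw):
    return build_panel(small_raw, apply_eligibility(small_raw))


@pytest.fixture(scope="session")
def truth_fit(truth, small_panel):
    """Ground-truth parameters wrapped as a fit (no sampling error)."""
    params, structure = truth
    return msm.MSMFit(
        params=params,
        structure=structure,
        covariance=None,
        loglik=np.nan,
        converged=True,
        grad_norm=0.0,
        n_patients=len(small_panel),
        n_transitions=small_panel.n_transitions_observed,
    )


def make_raw_bundle(patients=None, visits=None, weights=None, wmt_events=None, conditions=None):
    """Hand-built raw bundle with sensible empty defaults."""
    from weightmsm.cohort import RawEHRBundle

    return RawEHRBundle(
        patients=patients
        if patients is not None
        else pd.DataFrame(columns=["patient_id", "age", "sex", "race", "ethnicity", "height_m"]),
        visits=visits if visits is not None else pd.DataFrame(columns=["patient_id", "date"]),
        weights=weights
        if weights is not None
        else pd.DataFrame(columns=["patient_id", "date", "weight_kg"]),
        wmt_events=wmt_events
        if wmt_events is not None
        else pd.DataFrame(columns=["patient_id", "kind", "date", "end_date", "drug"]),
        conditions=conditions
        if conditions is not None
        else pd.DataFrame(columns=["patient_id", "condition", "date"]),
    )
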