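"""Shared fixtures.

The virtual-trial fixtures are session-scoped because each one simulates a
full LHS cohort; several acceptance checks (class fractions, responder
statistics, waterfall invariants) read the same trial.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from icbsim import ModelParams, PatientParameters
from icbsim import regimens
from icbsim.trials import run_trial, sample_cohort

TRIAL_SEED = 1


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    return ModelParams(patient=PatientParameters())


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


def _run(regimen, n, band=90.0):
    cohort = sample_cohort(n=n, seed=TRIAL_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_trial(cohort, regimen, band_level=band)


@pytest.fixture(scope="session")
def pd1_trial():
    """anti-PD-1 3 mg/kg Q2W, 200 virtual patients."""
    return _run(regimens.anti_pd1(3.0), 200)


@pytest.fixture(scope="session")
def ctla4_trial():
    """anti-CTLA-4 3 mg/kg Q3W x4, 200 virtual patients."""
    return _run(regimens.anti_ctla4(3.0), 200)


@pytest.fixture(scope="session")
def pdl1_trial():
    """anti-PD-L1 20 mg/kg Q2W, 200 virtual patients."""
    return _run(regimens.anti_pdl1(20.0), 200, band=30.0)


@pytest.fixture(scope="session")
def combo_trial():
    """anti-PD-1 1 mg/kg + anti-CTLA-4 3 mg/kg, 47 virtual patients."""
    return _run(regimens.combination(1.0, 3.0), 47)
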