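"""Shared fixtures: small axes, phantoms and a session-scoped default cohort."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from sersstroma import (
    BaselineParams,
    PeakSpec,
    WavenumberAxis,
    default_peak_library,
    make_phantom,
    render_cube,
)
from sersstroma.config import CohortConfig, PreprocessConfig
from sersstroma.pipeline import preprocess_patient, simulate_cohort


@pytest.fixture(scope="session")
def axis() -> WavenumberAxis:
    return WavenumberAxis()


@pytest.fixture(scope="session")
def short_axis() -> WavenumberAxis:
    return WavenumberAxis(300.0, 1200.0, 2.0)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom((16, 16), "IBC", seed=1)


@pytest.fixture(scope="session")
def flat_baseline() -> BaselineParams:
    return BaselineParams.flat()


@pytest.fixture(scope="session")
def default_cohort():
    """Default 14 DCIS + 32 IBC synthetic cohort, raw."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def processed_cohort(default_cohort):
    """The default cohort after calibration, binning and baseline removal."""
    pcfg = PreprocessConfig()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return [
            (p.patient_id, p.diagnosis, *preprocess_patient(p, pcfg))
            for p in default_cohort
        ]
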