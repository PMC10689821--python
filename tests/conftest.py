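"""Shared fixtures: synthetic cohorts and expensive end-to-end runs.

The heavyweight leave-one-out runs are session-scoped so the recovery
and leakage checks can share them.
"""

from __future__ import annotations

import datetime

import numpy as np
import pytest

from thyrowatch.hr_windows import SleepNight
from thyrowatch.synthetic import CohortConfig, generate_cohort, recovery_check

RECOVERY_SEEDS = (101, 102, 103, 104, 105)
NULL_SEEDS = (101, 102, 103)


def make_night(pid: str, date: datetime.date, mean: float, n: int = 120, seed: int = 0) -> SleepNight:
    rng = np.random.default_rng(seed)
    samples = tuple(np.clip(np.round(rng.normal(mean, 5.0, size=n)), 30, 220).tolist())
    return SleepNight(patient_id=pid, date=date, samples=samples)


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients with short nights: fast but structurally complete."""
    return generate_cohort(CohortConfig(n_patients=12, seed=7, night_length=(80, 120)))


@pytest.fixture(scope="session")
def sweep_cohort():
    """10 patients for the window-length sweep."""
    return generate_cohort(CohortConfig(n_patients=10, seed=42, night_length=(80, 120)))


@pytest.fixture(scope="session")
def recovery_runs():
    """Full pipeline on 40-patient cohorts with strong fT4-HR coupling."""
    return {
        seed: recovery_check(CohortConfig(n_patients=40, seed=seed))
        for seed in RECOVERY_SEEDS
    }


@pytest.fixture(scope="session")
def null_runs():
    """Full pipeline with the HR-fT4 coupling switched off."""
    return {
        seed: recovery_check(CohortConfig(n_patients=40, seed=seed, hr_coupling_slope=0.0))
        for seed in NULL_SEEDS
    }
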