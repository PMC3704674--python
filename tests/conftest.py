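"""Shared fixtures: a full-size default cohort, a session-wide replicate
study (reused by several tests to keep the suite fast), and a scaled-down
instrument config for unit tests that do not need the 5040-point grid."""

from __future__ import annotations

import numpy as np
import pytest

from vocsense import (SimulationConfig, StepwiseLDA, loocv, loocv_sweep,
                      simulate_cohort, standardize_cohort)
from vocsense.config import MarkerPeakSpec, PeakSpec, SecondaryEffect
from vocsense.evaluation import confusion

REPLICATE_SEEDS = list(range(1, 21))


def small_config(**overrides) -> SimulationConfig:
    """A 600-point instrument with four shared peaks and one marker.

    Same structure as the default study at ~1/8 the grid, for tests where
    runtime matters more than the exact instrument geometry.
    """
    params = dict(
        n_cancer=12,
        n_control=18,
        grid_length=600,
        shared_peaks=(
            PeakSpec(60.0, 8.0, 9.0),
            PeakSpec(150.0, 9.0, 8.0),
            PeakSpec(260.0, 10.0, 10.0),
            PeakSpec(420.0, 12.0, 7.0),
        ),
        marker_peak=MarkerPeakSpec(location=500.0, width_sd=10.0,
                                   amplitude_mean=8.0,
                                   prevalence_cancer=10.0 / 12.0),
        secondary_effects=(
            SecondaryEffect(60.0, 3.0),
            SecondaryEffect(260.0, -2.5),
            SecondaryEffect(420.0, 2.5),
        ),
        seed=0,
    )
    params.update(overrides)
    return SimulationConfig(**params)


def null_config(**overrides) -> SimulationConfig:
    """Small config with the group effects removed (both groups iid)."""
    cfg = small_config(**overrides)
    return cfg.replace(
        marker_peak=MarkerPeakSpec(location=500.0, width_sd=10.0,
                                   amplitude_mean=8.0,
                                   prevalence_cancer=0.0),
        secondary_effects=())


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size (24 cancer / 74 control, 5040-point) cohort, seed 1."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=3))


@pytest.fixture(scope="session")
def replicate_tables():
    """Both methods run end-to-end on 20 seeded default cohorts.

    Computed once per session; several tests consume different columns.
    Each entry holds the method-1 within-sample and LOO confusion matrices
    and the method-2 factor-sweep table.
    """
    out = {}
    for seed in REPLICATE_SEEDS:
        cohort = simulate_cohort(SimulationConfig(seed=seed))
        X = standardize_cohort(cohort)
        model = StepwiseLDA(max_features=9).fit(X, cohort.y)
        within = confusion(cohort.y, model.predict(X))
        cv = loocv(cohort, protocol="fixed_features", max_features=9)
        sweep = loocv_sweep(cohort, max_factors=10)
        out[seed] = {"within": within, "loo": cv, "sweep": sweep,
                     "n": len(cohort)}
    return out
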