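"""Shared fixtures: synthetic cohorts at the default study conditions and
small hand-constructed objects."""
from __future__ import annotations

import warnings

import numpy as np
import pytest

import floreyindex as fx


def make_series(pid, ages, scores, diagnoses=None, covariates=None):
    """Participant built from parallel age/score lists."""
    diagnoses = diagnoses or [None] * len(ages)
    visits = [
        fx.VisitRecord(pid, float(a), float(s),
                       diagnosis=fx.Stage(d) if isinstance(d, str) else d)
        for a, s, d in zip(ages, scores, diagnoses)
    ]
    return fx.ParticipantSeries(pid, visits, covariates or {})


def km_oracle(durations, observed):
    """Hand-coded product-limit estimator: independent check for km_estimate.

    Events precede censorings at tied times. Returns (event_times, survival).
    """
    durations = np.asarray(durations, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    times = np.unique(durations[observed])
    s = 1.0
    surv = []
    for t in times:
        n_at_risk = int((durations >= t).sum())
        d = int(((durations == t) & observed).sum())
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return times, np.array(surv)


@pytest.fixture(scope="session")
def truth_curve():
    return fx.calibrated_curve()


@pytest.fixture(scope="session")
def noisy_sim():
    """Default study conditions: n=500, observation noise SD 0.5, seed 1."""
    return fx.simulate_cohort(fx.SimulationConfig(n_participants=500, noise_sd=0.5, seed=1))


@pytest.fixture(scope="session")
def noisy_alignment(noisy_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fx.fit_alignment_model(noisy_sim.cohort)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free cohort: no observation noise, no grid rounding, seed 1."""
    return fx.simulate_cohort(
        fx.SimulationConfig(n_participants=500, noise_sd=0.0, round_to_grid=False, seed=1)
    )


@pytest.fixture(scope="session")
def clean_alignment(clean_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fx.fit_alignment_model(clean_sim.cohort)


@pytest.fixture(scope="session")
def default_model():
    return fx.default_model()
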