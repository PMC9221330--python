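"""Shared fixtures.

Cohort fixtures are session-scoped because generating and featurizing a
subject takes a few seconds; every test that needs cohort-level data reuses
these instead of building its own.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from physiofuse.features import FeatureMatrix, extract_features
from physiofuse.model import PipelineConfig
from physiofuse.synth import (
    SimPlan,
    default_profiles,
    default_schedule,
    simulate_cohort,
)


def _schedule(segment_s: float):
    return tuple((b, segment_s) for b, _ in default_schedule())


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def one_subject_set(profiles):
    """One subject, 150 s per behavior."""
    plan = SimPlan(subjects=1, schedule=_schedule(150.0), profiles=profiles, seed=7)
    return simulate_cohort(plan)[0]


@pytest.fixture(scope="session")
def one_subject_matrix(one_subject_set, config) -> FeatureMatrix:
    return extract_features(one_subject_set, config)


@pytest.fixture(scope="session")
def cohort6_matrix(profiles, config) -> FeatureMatrix:
    """Six subjects, 150 s segments: the default evaluation cohort."""
    plan = SimPlan(subjects=6, schedule=_schedule(150.0), profiles=profiles, seed=2)
    frames = [extract_features(r, config).frame for r in simulate_cohort(plan)]
    return FeatureMatrix(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def cohort14_matrix(profiles, config) -> FeatureMatrix:
    """The full 14-subject trend-recovery cohort, 180 s segments."""
    plan = SimPlan(subjects=14, schedule=_schedule(180.0), profiles=profiles, seed=1)
    frames = [extract_features(r, config).frame for r in simulate_cohort(plan)]
    return FeatureMatrix(pd.concat(frames, ignore_index=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
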