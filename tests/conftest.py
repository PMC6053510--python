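"""Shared fixtures: subject profiles, stitched walk/rest recordings, and the
session-scoped synthetic cohort experiment reused by the study-level tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import gaitspeed as gs
from gaitspeed.simulate import _Builder, _walk_world


@pytest.fixture(scope="session")
def cohort():
    return gs.make_cohort(32, seed=0)


@pytest.fixture(scope="session")
def low_profile(cohort):
    """A low-disability subject (EDSS 1.0, d = 0)."""
    p = next(p for p in cohort if p.edss == 1.0)
    return p


@pytest.fixture(scope="session")
def high_profile(cohort):
    return next(p for p in cohort if p.group == "high")


def make_activity_recording(profile, plan, rate=100.0, seed=123,
                            start=np.datetime64("2023-05-01T10:00:00")):
    """Build a continuous recording from a plan of ('walk', dur, speed) and
    ('rest', dur) blocks; returns (RawRecording, list of true walk sample
    windows)."""
    rng = np.random.default_rng(seed)
    b = _Builder(rate, start)
    windows = []
    for item in plan:
        if item[0] == "rest":
            b.rest(item[1])
        else:
            _, dur, speed = item
            world, _steps, _f = _walk_world(profile, speed, dur, rate, rng)
            windows.append(b.append(world))
    return b.render(profile, rng), windows


@pytest.fixture()
def walk_rest_recording(low_profile):
    """60 s walk flanked by 30 s of rest, with the true walk window."""
    rec, wins = make_activity_recording(
        low_profile, [("rest", 30.0), ("walk", 60.0, 1.2), ("rest", 30.0)]
    )
    return rec, wins[0]


@pytest.fixture(scope="session")
def small_model(low_profile):
    """A quick personalized model fit on a reduced calibration session."""
    rec, walks, _ = gs.simulate_calibration_session(
        low_profile, seed=42, validation_duration=30.0
    )
    uni = gs.resample_uniform(rec, 100.0)
    calib = [w for w in walks if w.walk_type in ("T25FW", "2MIN")]
    data = gs.build_training_set(uni, calib)
    model = gs.fit_model(data, scope="personalized", subject_id=low_profile.subject_id)
    return model, uni, walks, data


@pytest.fixture(scope="session")
def cohort_result():
    """The full synthetic study: 32 subjects, personalized + generic models.

    Session-scoped because it is the expensive end-to-end computation that
    the study-level assertions (correlations, group error tables, PCA
    separation) all share.
    """
    return gs.run_cohort_experiment(seed=0)


def replace_profile(p, **kw):
    return dataclasses.replace(p, **kw)
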