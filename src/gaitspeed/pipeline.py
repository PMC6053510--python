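"""End-to-end composition: recording -> bouts -> steps -> speeds -> summaries.

The library modules each do one stage; this module wires them together the
way the tool's commands (and the tests) use them, and provides the cohort
experiment that reproduces the study-level comparisons: personalized
versus generic model accuracy across disability groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    GaitModel,
    LabeledStep,
    SupervisedWalk,
    build_training_set,
    fit_model,
    predict_bout_speed,
)
from .errors import AlignmentWarning
from .home import (
    DAYTIME,
    HomeSummary,
    TimedBout,
    find_sustained_walks,
    summarize_home,
)
from .preprocess import (
    BoutConfig,
    WalkBout,
    detect_walking_bouts,
    filter_aligned,
    tilt_correct_and_align,
)
from .signal_io import UniformRecording, resample_uniform
from .simulate import (
    SubjectProfile,
    make_cohort,
    make_reference_cohort,
    simulate_calibration_session,
)
from .steps import StepFeatures, features_for_bout


def detect_bouts(
    rec: UniformRecording, config: BoutConfig = BoutConfig()
) -> list[WalkBout]:
    """Detect walking bouts across every contiguous segment of a recording.

    Each segment is coarsely gravity-aligned as a whole for detection (the
    horizontal orientation may be ambiguous on mostly-rest segments, which
    is harmless here — only the vertical channel and the magnitude feed the
    detector); the per-bout analysis re-aligns precisely later.
    """
    min_len = max(int(config.min_duration * rec.rate), int(2 * rec.rate) + 1)
    bouts: list[WalkBout] = []
    for s, e in rec.segments():
        if e - s < min_len:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AlignmentWarning)
            sig = tilt_correct_and_align(rec, (s, e))
        for b in detect_walking_bouts(sig, config):
            bouts.append(
                WalkBout(s + b.start_index, s + b.end_index, b.duration)
            )
    return bouts


def analyze_bout(
    rec: UniformRecording,
    bout: WalkBout,
    subject_id: str = "",
    bout_id: str = "",
) -> list[StepFeatures]:
    """Align, filter and featurise one bout of a recording."""
    sig = filter_aligned(
        tilt_correct_and_align(rec, (bout.start_index, bout.end_index))
    )
    local = WalkBout(0, sig.n_samples, sig.n_samples / sig.rate)
    _, feats = features_for_bout(sig, local, subject_id=subject_id, bout_id=bout_id)
    return feats


def calibrate_subject(
    rec: UniformRecording,
    walks: list[SupervisedWalk],
    grid: dict | None = None,
    seed: int = 0,
) -> GaitModel:
    """Build the training set from supervised walks and fit a personalized model."""
    data = build_training_set(rec, walks)
    sid = walks[0].subject_id if walks else None
    return fit_model(data, scope="personalized", subject_id=sid, grid=grid, seed=seed)


def estimate_walk_speed(
    rec: UniformRecording, window: tuple[int, int], model: GaitModel
) -> float:
    """Estimated mean speed of a known walk window (m/s)."""
    bout = WalkBout(window[0], window[1], (window[1] - window[0]) / rec.rate)
    feats = analyze_bout(rec, bout, subject_id=rec.subject_id)
    return predict_bout_speed(model, feats)


def monitor_recording(
    rec: UniformRecording,
    model: GaitModel,
    bout_config: BoutConfig = BoutConfig(),
    daytime_window: tuple[float, float] = DAYTIME,
) -> tuple[HomeSummary, pd.DataFrame]:
    """Full free-living analysis of a multi-day recording.

    Returns the per-subject :class:`HomeSummary` and a per-bout detail
    table (start time, duration, n steps, predicted speed, sustained flag).
    """
    bouts = detect_bouts(rec, bout_config)
    timed: list[TimedBout] = []
    rows = []
    for i, bout in enumerate(bouts):
        feats = analyze_bout(rec, bout, subject_id=rec.subject_id, bout_id=f"b{i:04d}")
        if not feats:
            continue
        speed = predict_bout_speed(model, feats)
        start = rec.time_of(bout.start_index)
        timed.append(TimedBout(bout, start, speed))
        rows.append(
            {
                "bout_id": f"b{i:04d}",
                "start_time": str(start.astype("datetime64[ms]")),
                "duration_s": bout.duration,
                "n_steps": len(feats),
                "speed_m_s": speed,
                "est_distance_m": speed * bout.duration,
            }
        )
    sustained = find_sustained_walks(timed, daytime_window)
    kept = {(str(w.start_time.astype("datetime64[ms]"))) for w in sustained}
    detail = pd.DataFrame(rows)
    if len(detail):
        detail["sustained"] = [r["start_time"] in kept for r in rows]
    summary = summarize_home(sustained, rec.subject_id)
    return summary, detail


# ---------------------------------------------------------------------------
# cohort-level experiment


@dataclass
class CohortResult:
    """Study-style comparison of personalized and generic models.

    ``table`` has one row per MS subject: EDSS, disability group, the true
    validation-walk speed and both models' estimates. ``labeled_steps``
    maps subject id to that subject's calibration steps (for PCA-style
    analyses); ``models`` holds the personalized models.
    """

    table: pd.DataFrame
    models: dict[str, GaitModel] = field(default_factory=dict)
    generic_model: GaitModel | None = None
    labeled_steps: dict[str, list[LabeledStep]] = field(default_factory=dict)
    profiles: dict[str, SubjectProfile] = field(default_factory=dict)


def _session_data(
    p: SubjectProfile, seed: int
) -> tuple[UniformRecording, list[SupervisedWalk], list[LabeledStep], SupervisedWalk]:
    rec, walks, _truth = simulate_calibration_session(p, seed=seed)
    uni = resample_uniform(rec, rate=100.0)
    calib = [w for w in walks if w.walk_type in ("T25FW", "2MIN")]
    validation = next(w for w in walks if w.walk_type == "free")
    labeled = build_training_set(uni, calib)
    return uni, calib, labeled, validation


def run_cohort_experiment(
    seed: int = 0,
    n_subjects: int = 32,
    n_reference: int = 7,
    grid: dict | None = None,
    max_steps_per_reference_subject: int = 150,
) -> CohortResult:
    """Simulate the full study and evaluate both modelling strategies.

    Every MS subject gets a personalized SVR model fit on their own 10
    calibration walks (leave-one-walk-out grid search); a single generic
    model is fit on steps pooled from ``n_reference`` healthy reference
    subjects (leave-one-subject-out folds, each subject's steps subsampled
    to at most ``max_steps_per_reference_subject`` so the long walks do not
    dominate). Both predict each subject's held-out validation walk.
    """
    cohort = make_cohort(n_subjects, seed=seed)
    reference = make_reference_cohort(n_reference, seed=seed)

    pooled: list[LabeledStep] = []
    rng = np.random.default_rng([seed, 777])
    for p in reference:
        _, _, labeled, _ = _session_data(p, seed=p.seed)
        if len(labeled) > max_steps_per_reference_subject:
            pick = rng.choice(
                len(labeled), size=max_steps_per_reference_subject, replace=False
            )
            labeled = [labeled[i] for i in sorted(pick)]
        pooled.extend(labeled)
    generic = fit_model(pooled, scope="generic", grid=grid, seed=seed)

    rows = []
    models: dict[str, GaitModel] = {}
    steps_by_subject: dict[str, list[LabeledStep]] = {}
    profiles: dict[str, SubjectProfile] = {}
    for p in cohort:
        uni, calib, labeled, validation = _session_data(p, seed=p.seed)
        model = fit_model(
            labeled, scope="personalized", subject_id=p.subject_id, grid=grid,
            seed=seed,
        )
        est_p = estimate_walk_speed(uni, validation.window, model)
        est_g = estimate_walk_speed(uni, validation.window, generic)
        rows.append(
            {
                "subject_id": p.subject_id,
                "edss": p.edss,
                "group": p.group,
                "true_speed": validation.speed,
                "personalized_speed": est_p,
                "generic_speed": est_g,
            }
        )
        models[p.subject_id] = model
        steps_by_subject[p.subject_id] = labeled
        profiles[p.subject_id] = p
    for p in reference:
        profiles[p.subject_id] = p
    return CohortResult(
        table=pd.DataFrame(rows),
        models=models,
        generic_model=generic,
        labeled_steps=steps_by_subject,
        profiles=profiles,
    )
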