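"""Support-vector-regression gait models: training, prediction, persistence.

A gait model maps the 29-feature step descriptor to walking speed (m/s).
*Personalized* models are trained on one subject's supervised calibration
walks (each step labelled with its walk's measured distance/time speed);
the *generic* model pools steps from a reference group of healthy walkers.
Features are z-scored with the training means/SDs, the kernel is a radial
basis function, and hyperparameters are chosen by grouped cross-validation
(leave-one-walk-out for personalized models; leave-one-subject-out for the
generic model, since its folds must respect subject identity) minimising
the pooled RMSE of held-out per-step predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR

from .errors import InsufficientCalibrationError, ModelCompatibilityError
from .steps import FEATURE_NAMES, N_FEATURES, StepFeatures

#: Default hyperparameter grid; gamma multipliers scale 1/(29 * Var(X)).
DEFAULT_GRID = {
    "C": (0.1, 1.0, 10.0, 100.0),
    "epsilon": (0.01, 0.05, 0.1),
    "gamma_scale": (1.0, 0.3, 3.0),
}


@dataclass(frozen=True)
class SupervisedWalk:
    """A supervised walk with measured distance and duration.

    ``window`` is the half-open sample range of the walk within the
    uniformly resampled recording. Speed is always distance/duration.
    """

    subject_id: str
    walk_id: str
    walk_type: str  # one of {"T25FW", "2MIN", "free"}
    distance: float  # m
    duration: float  # s
    window: tuple[int, int]

    def __post_init__(self):
        if self.distance <= 0 or self.duration <= 0:
            raise ValueError("distance and duration must be positive")
        if self.walk_type not in {"T25FW", "2MIN", "free"}:
            raise ValueError(f"unknown walk_type {self.walk_type!r}")

    @property
    def speed(self) -> float:
        return self.distance / self.duration


@dataclass(frozen=True)
class LabeledStep:
    """A step descriptor labelled with the speed of its containing walk."""

    features: StepFeatures
    label_speed: float
    walk_id: str

    def __post_init__(self):
        if self.label_speed <= 0:
            raise ValueError("label speed must be positive")


@dataclass
class GaitModel:
    """A trained gait-speed regressor with its standardisation and metadata."""

    scope: str  # "personalized" or "generic"
    subject_id: str | None
    feature_names: tuple[str, ...]
    mean: np.ndarray  # (29,)
    sd: np.ndarray  # (29,)
    C: float
    epsilon: float
    gamma: float
    support_vectors: np.ndarray  # (n_sv, 29), standardised space
    dual_coef: np.ndarray  # (n_sv,)
    intercept: float
    cv_report: dict[str, float] = field(default_factory=dict)  # fold -> RMSE
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (len(self.feature_names),) or self.sd.shape != (
            len(self.feature_names),
        ):
            raise ModelCompatibilityError(
                "standardisation arrays must match the feature names in length"
            )
        if len(self.feature_names) != N_FEATURES:
            raise ModelCompatibilityError(
                f"model has {len(self.feature_names)} features, expected {N_FEATURES}"
            )
        if not self.cv_report:
            raise ValueError("cv_report must be non-empty")

    # -- prediction ------------------------------------------------------

    def _decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.mean) / self.sd
        d2 = (
            np.sum(Xs**2, axis=1)[:, None]
            + np.sum(self.support_vectors**2, axis=1)[None, :]
            - 2.0 * Xs @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict speeds (m/s, clipped at 0) for rows of raw features."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != N_FEATURES:
            raise ModelCompatibilityError(
                f"expected {N_FEATURES} features, got {X.shape[1]}"
            )
        return np.clip(self._decision(X), 0.0, None)

    # -- persistence -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "gaitspeed-model",
            "version": 1,
            "scope": self.scope,
            "subject_id": self.subject_id,
            "feature_names": list(self.feature_names),
            "standardization": {"mean": self.mean.tolist(), "sd": self.sd.tolist()},
            "regressor": {
                "kernel": "rbf",
                "C": self.C,
                "epsilon": self.epsilon,
                "gamma": self.gamma,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coef": self.dual_coef.tolist(),
                "intercept": self.intercept,
            },
            "cv_report": self.cv_report,
            "training_meta": self.training_meta,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "GaitModel":
        try:
            reg = d["regressor"]
            std = d["standardization"]
            model = cls(
                scope=d["scope"],
                subject_id=d.get("subject_id"),
                feature_names=tuple(d["feature_names"]),
                mean=np.array(std["mean"], dtype=float),
                sd=np.array(std["sd"], dtype=float),
                C=float(reg["C"]),
                epsilon=float(reg["epsilon"]),
                gamma=float(reg["gamma"]),
                support_vectors=np.array(reg["support_vectors"], dtype=float),
                dual_coef=np.array(reg["dual_coef"], dtype=float),
                intercept=float(reg["intercept"]),
                cv_report=dict(d["cv_report"]),
                training_meta=dict(d.get("training_meta", {})),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelCompatibilityError(f"malformed model document: {exc}") from exc
        if tuple(model.feature_names) != FEATURE_NAMES:
            raise ModelCompatibilityError("model feature names do not match this package")
        return model

    @classmethod
    def load(cls, path) -> "GaitModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def build_training_set(
    rec, walks: list[SupervisedWalk]
) -> list[LabeledStep]:
    """Label every detected step inside each supervised walk's window.

    Each walk window of the uniformly resampled recording is independently
    tilt-corrected, 20 Hz filtered, and segmented into steps; every step is
    labelled with the walk's distance/duration speed. Walks yielding fewer
    than two steps are excluded with :class:`CalibrationWarning`.
    """
    import warnings

    from .errors import CalibrationWarning
    from .preprocess import WalkBout, filter_aligned, tilt_correct_and_align
    from .steps import features_for_bout

    if not walks:
        raise InsufficientCalibrationError("walk list is empty")
    labeled: list[LabeledStep] = []
    for walk in walks:
        sig = filter_aligned(tilt_correct_and_align(rec, walk.window))
        bout = WalkBout(0, sig.n_samples, sig.n_samples / sig.rate)
        steps, feats = features_for_bout(
            sig, bout, subject_id=walk.subject_id, bout_id=walk.walk_id
        )
        if len(steps) < 2:
            warnings.warn(
                f"walk {walk.walk_id} yielded {len(steps)} steps; excluded",
                CalibrationWarning,
                stacklevel=2,
            )
            continue
        labeled.extend(
            LabeledStep(f, walk.speed, walk.walk_id) for f in feats
        )
    return labeled


def _canonical_order(data: list[LabeledStep]) -> list[LabeledStep]:
    return sorted(
        data,
        key=lambda d: (
            d.walk_id,
            d.features.subject_id,
            d.features.bout_id,
            d.features.step_index,
        ),
    )


def fit_model(
    data: list[LabeledStep],
    scope: str = "personalized",
    subject_id: str | None = None,
    grid: dict | None = None,
    seed: int = 0,
    fold_by: str | None = None,
) -> GaitModel:
    """Fit a gait model with grouped-CV hyperparameter selection.

    Requires at least 30 labelled steps spanning at least two distinct
    label speeds. ``fold_by`` selects the CV grouping key: ``"walk"``
    (default for personalized scope) or ``"subject"`` (default for generic
    scope). The winning (C, epsilon, gamma) minimises pooled held-out RMSE,
    ties broken by grid order, and the final model is refit on all steps.
    Deterministic for identical data regardless of input row order (rows
    are canonically sorted first).
    """
    if len(data) < 30:
        raise InsufficientCalibrationError(
            f"need >= 30 labeled steps, got {len(data)}"
        )
    labels_all = {round(d.label_speed, 9) for d in data}
    if len(labels_all) < 2:
        raise InsufficientCalibrationError("need >= 2 distinct label speeds")
    if fold_by is None:
        fold_by = "subject" if scope == "generic" else "walk"
    grid = grid or DEFAULT_GRID

    data = _canonical_order(data)
    X = np.vstack([d.features.values for d in data])
    y = np.array([d.label_speed for d in data])
    if fold_by == "walk":
        groups = np.array([d.walk_id for d in data])
    else:
        groups = np.array([d.features.subject_id for d in data])

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd
    x_var = float(Xs.var())
    gamma_base = 1.0 / (N_FEATURES * x_var) if x_var > 0 else 1.0 / N_FEATURES

    folds = []
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < len(y):  # keep folds with a non-empty training side
            folds.append((str(g), mask))
    if len(folds) < 2:
        raise InsufficientCalibrationError("need >= 2 CV groups for fold selection")

    best = None
    for C in grid["C"]:
        for eps in grid["epsilon"]:
            for gm in grid["gamma_scale"]:
                gamma = gamma_base * gm
                resid = np.empty_like(y)
                for _, mask in folds:
                    svr = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
                    svr.fit(Xs[~mask], y[~mask])
                    resid[mask] = svr.predict(Xs[mask]) - y[mask]
                rmse = float(np.sqrt(np.mean(resid**2)))
                if best is None or rmse < best[0] - 1e-12:
                    best = (rmse, C, eps, gamma)
    _, C, eps, gamma = best

    cv_report = {}
    for name, mask in folds:
        svr = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
        svr.fit(Xs[~mask], y[~mask])
        cv_report[name] = float(
            np.sqrt(np.mean((svr.predict(Xs[mask]) - y[mask]) ** 2))
        )

    final = SVR(kernel="rbf", C=C, epsilon=eps, gamma=gamma)
    final.fit(Xs, y)
    return GaitModel(
        scope=scope,
        subject_id=subject_id,
        feature_names=FEATURE_NAMES,
        mean=mean,
        sd=sd,
        C=float(C),
        epsilon=float(eps),
        gamma=float(gamma),
        support_vectors=final.support_vectors_.copy(),
        dual_coef=final.dual_coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        cv_report=cv_report,
        training_meta={
            "n_steps": int(len(y)),
            "n_groups": int(len(folds)),
            "fold_by": fold_by,
            "seed": int(seed),
        },
    )


def predict_step_speed(model: GaitModel, f: StepFeatures) -> float:
    """Predicted speed (m/s, non-negative) for a single step."""
    return float(model.predict(f.values[None, :])[0])


def predict_bout_speed(model: GaitModel, steps: list[StepFeatures]) -> float:
    """Bout speed as the unweighted mean of per-step predictions."""
    if not steps:
        raise ValueError("bout speed needs at least one step")
    X = np.vstack([s.values for s in steps])
    return float(model.predict(X).mean())
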