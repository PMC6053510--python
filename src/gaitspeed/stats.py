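"""The analysis layer: T25FW conversion, Pearson, Bland-Altman, PCA, and
EDSS-group error tables.

Two reference tables from the MS validation cohort ship with the package:
``clinic_cohort`` (n = 32; EDSS, mean-of-8-trials T25FW time and the speed
derived from it) and ``home_monitoring`` (n = 22; clinic T25FW speed
alongside the maximum and mean sustained home gait speeds). They serve as
worked inputs for the analysis operations and as fixtures for tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib.resources import files

import numpy as np
import pandas as pd
from scipy import stats as ss
from sklearn.decomposition import PCA

#: T25FW course length, metres (25 ft).
T25FW_DISTANCE_M = 7.62

#: EDSS disability-group bounds: low 1.0-3.5, moderate 4.0-5.5, high >= 6.0.
EDSS_GROUPS = (("low", 1.0, 3.5), ("moderate", 4.0, 5.5), ("high", 6.0, 10.0))


def load_clinic_cohort() -> pd.DataFrame:
    """The n=32 clinic reference table (patient, EDSS, T25FW time, speed)."""
    return pd.read_csv(files("gaitspeed.data") / "clinic_cohort.csv")


def load_home_monitoring() -> pd.DataFrame:
    """The n=22 home-monitoring reference table (clinic/max/mean speeds)."""
    return pd.read_csv(files("gaitspeed.data") / "home_monitoring.csv")


def t25fw_speed(mean_time: float) -> float:
    """Gait speed (m/s) of a T25FW trial set: 7.62 m / mean time.

    The reporting layer rounds to one decimal for table display; the value
    returned here keeps full precision.
    """
    if mean_time <= 0:
        raise ValueError(f"mean time must be positive, got {mean_time}")
    return T25FW_DISTANCE_M / mean_time


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement of an estimate with a reference: bias and 95% limits."""

    bias: float  # mean(est - ref)
    sd: float  # sample SD of differences (n-1)
    loa_low: float
    loa_high: float


@dataclass
class PcaResult:
    scores: np.ndarray  # (n, 2) PC1/PC2 coordinates
    explained_variance: np.ndarray  # (2,) fractions of retained variance
    loadings: np.ndarray  # (2, n_kept) sign-fixed
    group_labels: np.ndarray | None
    kept_columns: np.ndarray  # indices of non-constant columns


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = ss.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def bland_altman(ref, est) -> BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement of ``est - ref`` differences."""
    ref = np.asarray(ref, dtype=float)
    est = np.asarray(est, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("series must have equal length")
    if len(ref) < 2:
        raise ValueError("need n >= 2")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


def pca_step_features(features: np.ndarray, group_labels=None) -> PcaResult:
    """First two principal components of z-scored step features.

    Constant columns are dropped with a warning before the decomposition.
    Each component's sign is fixed so its largest-magnitude loading is
    positive, making score plots reproducible.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a (steps x features) table with >= 3 steps")
    sd = X.std(axis=0, ddof=0)
    kept = np.where(sd > 0)[0]
    if len(kept) < X.shape[1]:
        warnings.warn(
            f"dropping {X.shape[1] - len(kept)} constant feature column(s)",
            UserWarning,
            stacklevel=2,
        )
    if len(kept) < 2:
        raise ValueError("need >= 2 non-constant columns")
    Z = (X[:, kept] - X[:, kept].mean(axis=0)) / sd[kept]
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    loadings = pca.components_.copy()
    for i in range(2):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PcaResult(
        scores=scores,
        explained_variance=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        group_labels=None if group_labels is None else np.asarray(group_labels),
        kept_columns=kept,
    )


def edss_group(edss: float) -> str:
    """Disability group of an EDSS score; scores below 1.0 map to low."""
    for name, lo, hi in EDSS_GROUPS:
        if lo <= edss <= hi:
            return name
    warnings.warn(
        f"EDSS {edss} outside all group bounds; assigning 'low'",
        UserWarning,
        stacklevel=2,
    )
    return "low"


def group_error_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) of measured, estimated and error speeds per EDSS group.

    ``records`` needs columns ``subject_id``, ``edss``, ``measured_speed``,
    ``estimated_speed``. Rows are overall/low/moderate/high; error is
    estimated - measured; SDs use the n-1 convention. Full precision is
    kept — round at display time (one decimal for speeds, two for errors).
    """
    req = {"subject_id", "edss", "measured_speed", "estimated_speed"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    df = records.copy()
    df["group"] = [edss_group(e) for e in df["edss"]]
    df["error"] = df["estimated_speed"] - df["measured_speed"]

    def _row(sub: pd.DataFrame, name: str) -> dict:
        return {
            "group": name,
            "n": len(sub),
            "measured_mean": sub["measured_speed"].mean(),
            "measured_sd": sub["measured_speed"].std(ddof=1),
            "estimated_mean": sub["estimated_speed"].mean(),
            "estimated_sd": sub["estimated_speed"].std(ddof=1),
            "error_mean": sub["error"].mean(),
            "error_sd": sub["error"].std(ddof=1),
        }

    rows = [_row(df, "overall")]
    rows += [_row(df[df["group"] == g], g) for g in ("low", "moderate", "high")]
    return pd.DataFrame(rows)
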