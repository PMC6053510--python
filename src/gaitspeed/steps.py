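"""Step segmentation and the 29-feature per-step descriptor.

Foot contact is marked by the peak of forward (AP) acceleration followed by
a positive-to-negative sign change; the intervals between consecutive such
contacts are steps. Boundary finding runs on an extra 3 Hz-smoothed copy of
the AP channel because zero-crossing rules are unstable at the full 20 Hz
bandwidth; the features themselves are always computed from the 20 Hz
channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .errors import DegenerateStepError
from .preprocess import AlignedSignal, FilterSpec, WalkBout, lowpass

#: Admissible step duration bounds, seconds.
MIN_STEP_S = 0.2
MAX_STEP_S = 2.0

#: Smoothing filter used only to locate step boundaries.
BOUNDARY_FILTER = FilterSpec(order=4, cutoff=3.0, zero_lag=True)

#: The fixed, ordered names of the 29 per-step features.
FEATURE_NAMES: tuple[str, ...] = (
    "step_duration",
    "mean_v",
    "mean_ml",
    "mean_ap",
    "sd_v",
    "sd_ml",
    "sd_ap",
    "min_v",
    "min_ml",
    "min_ap",
    "max_v",
    "max_ml",
    "max_ap",
    "rms_v",
    "rms_ml",
    "rms_ap",
    "range_v",
    "range_ml",
    "range_ap",
    "ap_peak",
    "ap_peak_time_frac",
    "signal_magnitude_area",
    "vertical_disp_amplitude",
    "corr_v_ml",
    "corr_v_ap",
    "corr_ml_ap",
    "ap_dominant_freq",
    "spectral_entropy",
    "jerk_rms",
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 29


@dataclass(frozen=True)
class Step:
    """Half-open sample interval of one step within an aligned signal."""

    start_index: int
    end_index: int
    duration: float

    def __post_init__(self):
        if not MIN_STEP_S <= self.duration <= MAX_STEP_S:
            raise ValueError(
                f"step duration {self.duration:.3f} s outside "
                f"[{MIN_STEP_S}, {MAX_STEP_S}] s"
            )


@dataclass
class StepFeatures:
    """Exactly 29 named real descriptors of one step."""

    subject_id: str
    bout_id: str
    step_index: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("features must be finite")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def segment_steps(sig: AlignedSignal, bout: WalkBout) -> list[Step]:
    """Split a walking bout into steps via AP peaks and zero crossings.

    Candidate peaks are positive local maxima of the 3 Hz-smoothed AP with
    height at least ``max(0.03 g, 0.5 x median candidate height)``; each
    accepted peak contributes the first subsequent positive-to-negative
    zero crossing as a foot-contact boundary. Intervals between consecutive
    boundaries outside [0.2, 2.0] s are discarded. Returned indices are
    absolute (into ``sig``). Fewer than two boundaries yields ``[]``.
    """
    ap = sig.ap[bout.start_index : bout.end_index]
    if len(ap) <= 3 * BOUNDARY_FILTER.order * 2:
        return []
    smooth = lowpass(ap, sig.rate, BOUNDARY_FILTER)
    peaks, props = sps.find_peaks(smooth, height=0.0)
    if len(peaks) == 0:
        return []
    heights = props["peak_heights"]
    threshold = max(0.03, 0.5 * float(np.median(heights)))
    peaks = peaks[heights >= threshold]

    boundaries: list[int] = []
    neg = smooth <= 0.0
    for p in peaks:
        after = np.nonzero(neg[p + 1 :])[0]
        if len(after) == 0:
            continue
        b = p + 1 + int(after[0])
        if not boundaries or b != boundaries[-1]:
            boundaries.append(b)
    steps = []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        dur = (b - a) / sig.rate
        if MIN_STEP_S <= dur <= MAX_STEP_S:
            steps.append(Step(bout.start_index + a, bout.start_index + b, dur))
    return steps


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # (numerically) zero-variance channels get correlation 0 so vectors stay
    # finite and meaningful on degenerate steps
    tol_a = 1e-12 * max(1.0, float(np.max(np.abs(a))))
    tol_b = 1e-12 * max(1.0, float(np.max(np.abs(b))))
    if np.std(a) <= tol_a or np.std(b) <= tol_b:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _spectral_entropy(x: np.ndarray, rate: float) -> float:
    """Shannon entropy of the normalised periodogram, scaled to [0, 1]."""
    x = x - x.mean()
    if not np.any(x):
        return 0.0
    psd = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    psd = psd[1:]  # drop DC
    total = psd.sum()
    if total <= 0 or len(psd) < 2:
        return 0.0
    p = psd / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(len(psd)))


def _dominant_freq(x: np.ndarray, rate: float) -> float:
    x = x - x.mean()
    if not np.any(x):
        return 0.0
    psd = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    psd[0] = 0.0
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    return float(freqs[int(np.argmax(psd))])


def extract_features(
    sig: AlignedSignal,
    step: Step,
    subject_id: str = "",
    bout_id: str = "",
    step_index: int = 0,
) -> StepFeatures:
    """Compute the 29-feature descriptor of one step.

    Temporal and statistical features use the step's own samples of the
    20 Hz-filtered V/ML/AP channels; the two spectral features (dominant AP
    frequency and magnitude spectral entropy) use a 4 s window centred on
    the step, clipped to the signal bounds, so that short steps still have
    usable frequency resolution.
    """
    s, e = step.start_index, step.end_index
    if e - s < 3:
        raise DegenerateStepError(f"step [{s}, {e}) has fewer than 3 samples")
    dt = 1.0 / sig.rate
    v, ml, ap = sig.v[s:e], sig.ml[s:e], sig.ap[s:e]
    chans = (v, ml, ap)

    # vertical displacement: twice-integrated demeaned V, drift limited by
    # demeaning the intermediate velocity as well
    v_dm = v - v.mean()
    vel = cumulative_trapezoid(v_dm, dx=dt, initial=0.0)
    vel -= vel.mean()
    disp = cumulative_trapezoid(vel, dx=dt, initial=0.0)

    mag = np.sqrt(v**2 + ml**2 + ap**2)
    jerk = np.diff(mag) / dt

    half = int(round(2.0 * sig.rate))
    mid = (s + e) // 2
    ws, we = max(0, mid - half), min(sig.n_samples, mid + half)
    ap_win = sig.ap[ws:we]
    mag_win = np.sqrt(sig.v[ws:we] ** 2 + sig.ml[ws:we] ** 2 + sig.ap[ws:we] ** 2)

    i_peak = int(np.argmax(ap))
    values = [
        step.duration,
        *(float(c.mean()) for c in chans),
        *(float(c.std(ddof=1)) for c in chans),
        *(float(c.min()) for c in chans),
        *(float(c.max()) for c in chans),
        *(float(np.sqrt(np.mean((c - c.mean()) ** 2))) for c in chans),
        *(float(np.ptp(c)) for c in chans),
        float(ap.max()),
        i_peak * dt / step.duration,
        float(np.mean(np.abs(v) + np.abs(ml) + np.abs(ap))),
        float(np.ptp(disp)),
        _safe_corr(v, ml),
        _safe_corr(v, ap),
        _safe_corr(ml, ap),
        _dominant_freq(ap_win, sig.rate),
        _spectral_entropy(mag_win, sig.rate),
        float(np.sqrt(np.mean(jerk**2))) if len(jerk) else 0.0,
    ]
    return StepFeatures(subject_id, bout_id, step_index, np.array(values))


def features_for_bout(
    sig: AlignedSignal,
    bout: WalkBout,
    subject_id: str = "",
    bout_id: str = "",
) -> tuple[list[Step], list[StepFeatures]]:
    """Segment a bout and extract features for every step in it."""
    steps = segment_steps(sig, bout)
    feats = [
        extract_features(sig, st, subject_id, bout_id, i)
        for i, st in enumerate(steps)
    ]
    return steps, feats
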