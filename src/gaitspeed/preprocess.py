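"""Tilt correction, anatomical axis alignment, filtering, bout detection.

A lower-back accelerometer is attached at an arbitrary tilt, so the device
axes bear no fixed relation to the anatomical vertical (V), mediolateral
(ML) and anteroposterior (AP) directions. Alignment proceeds in two stages:
the mean acceleration over the analysis window estimates the gravity
direction (defining V), and the first principal direction of the residual
horizontal acceleration defines AP, with ML as the right-handed complement.
The AP sign is fixed by requiring non-negative skewness of the AP series —
forward trunk acceleration during gait is sharply peaked in the push-off
direction, so the physically forward orientation is the positively skewed
one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import skew

from .errors import AlignmentWarning, SignalQualityWarning, TooShortError
from .signal_io import UniformRecording


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification; ``zero_lag`` runs it forward-backward."""

    order: int = 4
    cutoff: float = 20.0
    zero_lag: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


#: The gait noise-removal filter: fourth-order zero-lag Butterworth at 20 Hz.
GAIT_FILTER = FilterSpec(order=4, cutoff=20.0, zero_lag=True)


@dataclass
class AlignedSignal:
    """Signal rotated into anatomical axes with gravity removed from V."""

    rate: float
    v: np.ndarray
    ml: np.ndarray
    ap: np.ndarray
    gravity_removed: bool
    window: tuple[int, int]  # [start, end) into the source UniformRecording
    rotation: np.ndarray | None = None  # device frame -> anatomical frame

    @property
    def n_samples(self) -> int:
        return self.v.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.v**2 + self.ml**2 + self.ap**2)


@dataclass(frozen=True)
class WalkBout:
    """Half-open sample interval ``[start_index, end_index)`` of walking."""

    start_index: int
    end_index: int
    duration: float

    def __post_init__(self):
        if self.end_index <= self.start_index:
            raise ValueError("bout end must exceed start")


@dataclass(frozen=True)
class BoutConfig:
    """Walking-bout detector parameters.

    A sliding window is labelled active when the SD of the gravity-removed
    acceleration magnitude exceeds ``std_threshold`` and the dominant
    frequency of the vertical channel falls in the locomotor band
    ``[freq_min, freq_max]``.
    """

    window: float = 2.0  # s, 50% overlap
    std_threshold: float = 0.05  # g
    freq_min: float = 0.5  # Hz
    freq_max: float = 3.0  # Hz
    bridge_gap: float = 1.0  # s, gaps between active runs shorter than this merge
    min_duration: float = 5.0  # s


def estimate_gravity(segment: np.ndarray) -> np.ndarray:
    """Unit gravity direction (device frame) from the mean of a window.

    At rest or during steady gait the cyclic accelerations average out and
    the mean vector points along the 1 g reaction to gravity. A mean far
    from 1 g (outside 0.5–1.5 g) suggests freefall or sustained shaking and
    raises :class:`SignalQualityWarning`.
    """
    mean = np.asarray(segment, dtype=float).reshape(-1, 3).mean(axis=0)
    mag = float(np.linalg.norm(mean))
    if not 0.5 <= mag <= 1.5:
        warnings.warn(
            f"mean acceleration magnitude {mag:.3f} g outside [0.5, 1.5] g; "
            "device likely in freefall or shaken",
            SignalQualityWarning,
            stacklevel=2,
        )
    if mag == 0.0:
        return np.array([0.0, 0.0, 1.0])
    return mean / mag


def _rotation_to_vertical(g: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping unit vector ``g`` onto ``(0, 0, 1)``."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(g, z)
    s = np.linalg.norm(v)
    c = float(g @ z)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def tilt_correct_and_align(
    rec: UniformRecording, window: tuple[int, int]
) -> AlignedSignal:
    """Rotate a window of a recording into anatomical V/ML/AP axes.

    Steps: (1) rotate so the estimated gravity direction becomes vertical
    and subtract the 1 g offset; (2) take AP as the first principal
    direction of the horizontal acceleration, signed so its skewness is
    non-negative; (3) take ML as the right-handed complement ``v x ap``.
    If the horizontal covariance is nearly isotropic (principal-variance
    ratio < 1.2) the orientation is ambiguous: a warning is raised and the
    rotated device order is kept.
    """
    start, end = window
    if (end - start) < 2 * rec.rate:
        raise ValueError("alignment window must cover >= 2 s")
    a = rec.data[start:end]
    g = estimate_gravity(a)
    rot = _rotation_to_vertical(g)
    r = a @ rot.T
    v = r[:, 2] - 1.0
    horiz = r[:, :2] - r[:, :2].mean(axis=0)
    cov = horiz.T @ horiz / max(len(horiz) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    ratio = evals[1] / max(evals[0], 1e-30)
    if ratio < 1.2:
        warnings.warn(
            f"horizontal principal-variance ratio {ratio:.2f} < 1.2; "
            "AP/ML orientation ambiguous, keeping device order",
            AlignmentWarning,
            stacklevel=2,
        )
        ap_dir = np.array([1.0, 0.0])
    else:
        ap_dir = evecs[:, 1]
    ap = horiz @ ap_dir
    if np.std(ap) > 1e-12 and skew(ap) < 0:
        ap_dir = -ap_dir
        ap = -ap
    # right-handed: ml = vertical x ap  (in the rotated frame vertical = e_z)
    ml_dir = np.array([-ap_dir[1], ap_dir[0]])
    ml = horiz @ ml_dir
    full_rot = (
        np.array(
            [
                [ap_dir[0], ap_dir[1], 0.0],
                [ml_dir[0], ml_dir[1], 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        @ rot
    )
    return AlignedSignal(
        rate=rec.rate,
        v=v,
        ml=ml,
        ap=ap,
        gravity_removed=True,
        window=(start, end),
        rotation=full_rot,
    )


def lowpass(x: np.ndarray, rate: float, spec: FilterSpec = GAIT_FILTER) -> np.ndarray:
    """Apply the Butterworth low-pass of ``spec``; zero-lag uses filtfilt."""
    x = np.asarray(x, dtype=float)
    if spec.cutoff >= rate / 2:
        raise ValueError(f"cutoff {spec.cutoff} Hz must be < Nyquist {rate / 2} Hz")
    if len(x) <= 3 * spec.order * (2 if spec.zero_lag else 1):
        raise TooShortError(
            f"series of length {len(x)} too short for order-{spec.order} filter"
        )
    sos = sps.butter(spec.order, spec.cutoff, btype="low", fs=rate, output="sos")
    if spec.zero_lag:
        return sps.sosfiltfilt(sos, x)
    return sps.sosfilt(sos, x)


def filter_aligned(sig: AlignedSignal, spec: FilterSpec = GAIT_FILTER) -> AlignedSignal:
    """Return a copy of ``sig`` with all three channels low-pass filtered."""
    return AlignedSignal(
        rate=sig.rate,
        v=lowpass(sig.v, sig.rate, spec),
        ml=lowpass(sig.ml, sig.rate, spec),
        ap=lowpass(sig.ap, sig.rate, spec),
        gravity_removed=sig.gravity_removed,
        window=sig.window,
        rotation=sig.rotation,
    )


def _dominant_frequency(x: np.ndarray, rate: float) -> float:
    """Frequency of the largest non-DC periodogram peak of a short window."""
    x = x - x.mean()
    if not np.any(x):
        return 0.0
    w = np.hanning(len(x))
    spec = np.abs(np.fft.rfft(x * w)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / rate)
    spec[0] = 0.0
    return float(freqs[int(np.argmax(spec))])


def detect_walking_bouts(
    sig: AlignedSignal, config: BoutConfig = BoutConfig()
) -> list[WalkBout]:
    """Find periods of walking in a gravity-removed aligned signal.

    Sliding windows (50% overlap) are labelled active by the magnitude-SD
    and vertical-dominant-frequency rules of :class:`BoutConfig`;
    consecutive active samples are merged, sub-``bridge_gap`` gaps bridged,
    and bouts shorter than ``min_duration`` discarded. An empty list is a
    valid result.
    """
    if not sig.gravity_removed:
        raise ValueError("bout detection requires a gravity-removed signal")
    n = sig.n_samples
    win = int(round(config.window * sig.rate))
    hop = max(win // 2, 1)
    if n < win:
        return []
    mag = sig.magnitude()
    active = np.zeros(n, dtype=bool)
    for s in range(0, n - win + 1, hop):
        seg = slice(s, s + win)
        if np.std(mag[seg]) <= config.std_threshold:
            continue
        fdom = _dominant_frequency(sig.v[seg], sig.rate)
        if config.freq_min <= fdom <= config.freq_max:
            active[seg] = True

    # runs of active samples
    edges = np.diff(active.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(n)
    runs = list(zip(starts, ends))
    # bridge short gaps
    bridge = int(round(config.bridge_gap * sig.rate))
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] < bridge:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = config.min_duration * sig.rate
    return [
        WalkBout(s, e, (e - s) / sig.rate) for s, e in merged if (e - s) >= min_len
    ]
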