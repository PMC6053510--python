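"""Synthetic lower-back accelerometry with ground truth.

The generator emulates the study design the estimator targets: a cohort of
MS subjects spanning EDSS 1-6 (20 low / 6 moderate / 6 high disability by
default) plus a small healthy reference group, each with a supervised
calibration session (8 timed 25-foot walks, 2 two-minute walks, 1
validation walk) and multi-day home recordings with a truth log.

The gait waveform is a phenomenological sinusoid mixture, not a
biomechanical simulation: its job is to exercise the detection premise (a
forward-acceleration peak followed by a positive-to-negative zero crossing
once per step) and to carry a disability-dependent cadence-speed
relationship, ``f = c0 + c1 * v`` with ``c0`` rising with disability.
Because more disabled walkers take faster, shorter steps at a given speed,
a model calibrated on healthy walkers systematically overestimates their
speed — the failure mode the personalized calibration exists to fix.

The AP channel is ``kAP*v*f*[sin(theta) + 0.3*sin(2*theta - pi/2)]`` with
per-step phase ``theta``: the second-harmonic phase of -pi/2 gives the
series positive skewness (so the forward-axis sign rule is well posed)
while keeping exactly one positive peak and one downward zero crossing per
step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import SupervisedWalk
from .errors import ConfigError
from .signal_io import RawRecording

#: EDSS scores sampled per disability group.
_GROUP_EDSS = {
    "low": (1.0, 1.5, 2.0, 2.5, 3.0, 3.5),
    "moderate": (4.0, 4.5, 5.0, 5.5),
    "high": (6.0,),
}

#: Default cohort composition for n=32 (low, moderate, high).
_GROUP_RATIO = (20, 6, 6)

DEFAULT_RATE = 100.0
_EPOCH = np.datetime64("2023-05-01T09:00:00", "ns")


@dataclass(frozen=True)
class SubjectProfile:
    """Gait parameters of one synthetic subject.

    ``disability`` d in [0, 1] maps linearly to EDSS (d=0 -> 1, d=1 -> 6).
    Cadence follows ``f = c0 + c1*v`` with the intercept rising with d;
    amplitude gains ``k_v``/``k_ap`` (g·s/m) fall with d; step-time jitter
    ``sigma_t`` rises with d. ``tilt`` is the fixed device-mounting
    rotation (<= 30 degrees off-vertical).
    """

    subject_id: str
    disability: float
    edss: float
    group: str
    preferred_speed: float  # m/s
    c0: float  # Hz
    c1: float  # Hz per (m/s)
    k_v: float  # g*s/m
    k_ap: float  # g*s/m
    sigma_t: float
    tilt: np.ndarray  # (3,3) world->device rotation
    noise_sd: float  # g
    seed: int


@dataclass(frozen=True)
class WalkTruth:
    """Ground truth for one simulated walk."""

    start_time: np.datetime64
    duration: float
    speed: float  # true mean speed, m/s
    cadence: float  # steps/s
    step_length: float  # m = speed / cadence
    step_times: np.ndarray  # start offset (s) of each whole step

    @property
    def n_steps(self) -> int:
        return len(self.step_times)

    @property
    def distance(self) -> float:
        return self.speed * self.duration


@dataclass
class TruthLog:
    walks: list[WalkTruth] = field(default_factory=list)


def _profile_from_edss(sid: str, edss: float, group: str, rng) -> SubjectProfile:
    d = max((edss - 1.0) / 5.0, 0.0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(np.deg2rad(5), np.deg2rad(30))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    tilt = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return SubjectProfile(
        subject_id=sid,
        disability=d,
        edss=edss,
        group=group,
        preferred_speed=float(np.clip(rng.normal(1.6 - 1.2 * d, 0.08), 0.4, 1.7)),
        c0=1.2 + 0.8 * d,
        c1=0.9 * (1 + rng.uniform(-0.1, 0.1)),
        k_v=0.35 * (1 - 0.4 * d) * (1 + rng.uniform(-0.15, 0.15)),
        k_ap=0.25 * (1 - 0.3 * d) * (1 + rng.uniform(-0.15, 0.15)),
        sigma_t=0.02 + 0.08 * d,
        tilt=tilt,
        noise_sd=0.02,
        seed=int(rng.integers(2**31)),
    )


def _group_sizes(n: int) -> dict[str, int]:
    total = sum(_GROUP_RATIO)
    raw = [n * r / total for r in _GROUP_RATIO]
    sizes = [int(np.floor(x)) for x in raw]
    rem = n - sum(sizes)
    order = np.argsort([s - x for s, x in zip(sizes, raw)])
    for i in range(rem):
        sizes[order[i]] += 1
    return dict(zip(("low", "moderate", "high"), sizes))


def make_cohort(n: int = 32, seed: int = 0) -> list[SubjectProfile]:
    """An MS-like cohort; at n=32 the groups are exactly 20/6/6."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, 101])
    profiles = []
    i = 0
    for group, size in _group_sizes(n).items():
        choices = _GROUP_EDSS[group]
        for _ in range(size):
            i += 1
            edss = float(choices[int(rng.integers(len(choices)))])
            profiles.append(_profile_from_edss(f"MS{i:02d}", edss, group, rng))
    return profiles


def make_reference_cohort(n: int = 7, seed: int = 0) -> list[SubjectProfile]:
    """Healthy reference walkers (disability ~ 0) for the generic model."""
    rng = np.random.default_rng([seed, 202])
    out = []
    for i in range(n):
        edss = 1.0 + float(rng.uniform(0.0, 0.75))  # d in [0, 0.15]
        out.append(_profile_from_edss(f"HV{i + 1:02d}", edss, "healthy", rng))
    return out


def _step_periods(f: float, duration: float, sigma_t: float, rng) -> np.ndarray:
    """Jittered per-step periods of the whole steps fitting in ``duration``."""
    base = 1.0 / f
    periods = []
    t = 0.0
    while True:
        T = base * (1.0 + sigma_t * rng.normal()) if sigma_t > 0 else base
        T = float(np.clip(T, 0.5 * base, 1.5 * base))
        if t + T > duration + 1e-9:
            break
        periods.append(T)
        t += T
    return np.array(periods)


def _walk_world(p: SubjectProfile, speed: float, duration: float, rate: float, rng):
    """World-frame (AP, ML, V) gait signal and step-boundary offsets."""
    f = p.c0 + p.c1 * speed
    periods = _step_periods(f, duration, p.sigma_t, rng)
    bounds = np.concatenate([[0.0], np.cumsum(periods)])
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    # assign each sample to a step; tail samples keep the last step's period
    idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, len(periods) - 1)
    theta = 2 * np.pi * (t - bounds[idx]) / periods[idx]
    theta_total = 2 * np.pi * idx + theta

    phi_v = rng.uniform(0, 2 * np.pi)
    phi_ml = rng.uniform(0, 2 * np.pi)
    amp = speed * f
    ap = p.k_ap * amp * (np.sin(theta) + 0.3 * np.sin(2 * theta - np.pi / 2))
    v = p.k_v * amp * np.sin(theta + phi_v)
    ml = (
        0.5
        * p.k_ap
        * amp
        * (1 + 0.8 * p.disability)
        * np.sin(0.5 * theta_total + phi_ml)
    )
    world = np.column_stack([ap, ml, v])
    return world, bounds[:-1], f


class _Builder:
    """Accumulates world-frame blocks on a wall clock, then renders a device
    recording (tilt rotation + gravity + sensor noise)."""

    def __init__(self, rate: float, start: np.datetime64):
        self.rate = rate
        self.clock = np.datetime64(start, "ns")
        self.times: list[np.ndarray] = []
        self.blocks: list[np.ndarray] = []
        self.n = 0

    def append(self, world: np.ndarray) -> tuple[int, int]:
        n = len(world)
        step_ns = int(round(1e9 / self.rate))
        ts = self.clock + (np.arange(n) * step_ns).astype("timedelta64[ns]")
        self.times.append(ts)
        self.blocks.append(world)
        self.clock = ts[-1] + np.timedelta64(step_ns, "ns")
        w = (self.n, self.n + n)
        self.n += n
        return w

    def rest(self, duration: float) -> tuple[int, int]:
        return self.append(np.zeros((int(round(duration * self.rate)), 3)))

    def skip_to(self, when: np.datetime64) -> None:
        when = np.datetime64(when, "ns")
        if when > self.clock:
            self.clock = when

    def skip(self, seconds: float) -> None:
        self.clock = self.clock + np.timedelta64(int(round(seconds * 1e9)), "ns")

    def render(self, p: SubjectProfile, rng) -> RawRecording:
        world = np.vstack(self.blocks)
        world[:, 2] += 1.0  # gravity reaction along world up
        dev = world @ p.tilt.T
        dev += rng.normal(0.0, p.noise_sd, size=dev.shape)
        return RawRecording(p.subject_id, np.concatenate(self.times), dev)


def simulate_walk(
    p: SubjectProfile,
    target_speed: float,
    duration: float,
    rate: float = DEFAULT_RATE,
    seed: int | None = None,
    start_time: np.datetime64 = _EPOCH,
) -> tuple[RawRecording, TruthLog]:
    """One continuous walk at ``target_speed`` m/s, with truth log."""
    if not 0.2 <= target_speed <= 2.0:
        raise ValueError("target speed must lie in [0.2, 2.0] m/s")
    if rate < 50:
        raise ConfigError("rate must be >= 50 Hz")
    rng = np.random.default_rng([seed if seed is not None else p.seed, 1])
    b = _Builder(rate, start_time)
    world, steps, f = _walk_world(p, target_speed, duration, rate, rng)
    b.append(world)
    rec = b.render(p, rng)
    truth = TruthLog(
        [
            WalkTruth(
                start_time=np.datetime64(start_time, "ns"),
                duration=duration,
                speed=target_speed,
                cadence=f,
                step_length=target_speed / f,
                step_times=steps,
            )
        ]
    )
    return rec, truth


def simulate_rest(
    p: SubjectProfile,
    duration: float,
    rate: float = DEFAULT_RATE,
    seed: int | None = None,
    start_time: np.datetime64 = _EPOCH,
) -> RawRecording:
    """Gravity plus sensor noise only (device worn, wearer at rest)."""
    rng = np.random.default_rng([seed if seed is not None else p.seed, 2])
    b = _Builder(rate, start_time)
    b.rest(duration)
    return b.render(p, rng)


def simulate_calibration_session(
    p: SubjectProfile,
    seed: int | None = None,
    rate: float = DEFAULT_RATE,
    start_time: np.datetime64 = _EPOCH,
    validation_duration: float = 60.0,
) -> tuple[RawRecording, list[SupervisedWalk], TruthLog]:
    """The supervised clinic protocol: 8 T25FW + 2 two-minute walks, then
    one free validation walk, separated by short rests.

    T25FW distances are exactly 7.62 m with ~8% trial-to-trial speed
    variation; longer walks vary by ~5%. The returned walk windows are
    sample ranges into the (uniform-rate) recording, and walk distances and
    durations match the truth log exactly.
    """
    rng = np.random.default_rng([seed if seed is not None else p.seed, 3])
    b = _Builder(rate, start_time)
    walks: list[SupervisedWalk] = []
    truth = TruthLog()
    b.rest(5.0)

    plan = [("T25FW", None, 0.08)] * 8 + [("2MIN", 120.0, 0.05)] * 2
    plan.append(("free", validation_duration, 0.05))
    for k, (wtype, dur, cv) in enumerate(plan):
        speed = float(np.clip(p.preferred_speed * (1 + cv * rng.normal()), 0.25, 1.95))
        if wtype == "T25FW":
            distance = 7.62
            dur = distance / speed
        else:
            distance = speed * dur
        t0 = b.clock
        world, steps, f = _walk_world(p, speed, dur, rate, rng)
        window = b.append(world)
        walks.append(
            SupervisedWalk(
                subject_id=p.subject_id,
                walk_id=f"{p.subject_id}-w{k:02d}-{wtype}",
                walk_type=wtype,
                distance=distance,
                duration=dur,
                window=window,
            )
        )
        truth.walks.append(
            WalkTruth(t0, dur, speed, f, speed / f, steps)
        )
        b.rest(8.0)
    return b.render(p, rng), walks, truth


def simulate_home_days(
    p: SubjectProfile,
    n_days: int = 3,
    seed: int | None = None,
    rate: float = DEFAULT_RATE,
    start_date: np.datetime64 = np.datetime64("2023-05-01"),
) -> tuple[RawRecording, TruthLog]:
    """Free-living days: 10-40 daytime walks per day with rests between.

    Walks occur only between 07:00 and 22:00 local; nights contain only
    brief rest snippets. The recording is written sparsely — idle stretches
    between activity blocks appear as timestamp gaps, which the resampler
    turns into segment breaks rather than fabricated samples. Some walks
    fall below the 7.62 m sustained-walk gate by construction (durations
    run down to 5 s).
    """
    if not 1 <= n_days <= 14:
        raise ValueError("n_days must be in [1, 14]")
    if rate < 50:
        raise ConfigError("rate must be >= 50 Hz")
    rng = np.random.default_rng([seed if seed is not None else p.seed, 4])
    day0 = np.datetime64(start_date, "D")
    b = _Builder(rate, np.datetime64(day0, "ns") + np.timedelta64(7, "h"))
    truth = TruthLog()
    for day in range(n_days):
        day_start = np.datetime64(day0 + day, "ns")
        b.skip_to(day_start + np.timedelta64(7, "h"))
        b.skip(float(rng.uniform(60, 1200)))
        n_walks = int(rng.integers(10, 41))
        day_end = day_start + np.timedelta64(22, "h")
        for _ in range(n_walks):
            dur = float(rng.uniform(5.0, 120.0))
            if b.clock + np.timedelta64(int((dur + 10) * 1e9), "ns") > day_end:
                break
            # sustained home walking clusters at or below the preferred
            # clinic pace (T25FW is a near-maximal self-paced test), so the
            # multiplicative spread is truncated just above 1
            factor = float(np.clip(1 + 0.12 * rng.normal(), 0.55, 1.06))
            speed = float(np.clip(p.preferred_speed * factor, 0.25, 1.95))
            b.rest(4.0)
            t0 = b.clock
            world, steps, f = _walk_world(p, speed, dur, rate, rng)
            b.append(world)
            truth.walks.append(WalkTruth(t0, dur, speed, f, speed / f, steps))
            b.rest(4.0)
            b.skip(float(rng.uniform(60, 900)))
        # night: two brief worn-at-rest snippets, never any walking
        b.skip_to(day_start + np.timedelta64(23, "h"))
        b.rest(60.0)
        b.skip_to(day_start + np.timedelta64(27, "h"))
        b.rest(60.0)
    return b.render(p, rng), truth
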