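"""Reading, writing and regularising raw accelerometer recordings.

The on-disk dialect is the plain CSV export produced by the AX3-GUI tool for
Axivity AX3 devices: one sample per row, an optional ``timestamp,ax,ay,az``
header, ISO-8601 timestamps (a trailing fractional-seconds field is
accepted), and the three device-frame accelerations in units of g.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, ParseError

#: Minimum admissible uniform sampling rate: the 20 Hz gait low-pass filter
#: needs more than twice its cutoff of headroom.
MIN_RATE_HZ = 50.0

#: AX3 dynamic range, in g.
MAX_ABS_G = 16.0


@dataclass
class RawRecording:
    """Timestamped tri-axial acceleration as exported from the device.

    Parameters
    ----------
    subject_id
        Identifier of the wearer.
    time
        ``datetime64[ns]`` array of sample timestamps, strictly increasing.
    accel
        ``(n, 3)`` array of device-frame accelerations in g.
    """

    subject_id: str
    time: np.ndarray
    accel: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype="datetime64[ns]")
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        n = self.time.shape[0]
        if n < 2:
            raise EmptyInputError(f"recording needs >= 2 samples, got {n}")
        if self.accel.shape != (n, 3):
            raise ValueError(f"accel must be (n, 3); got {self.accel.shape} for n={n}")
        if not np.all(np.diff(self.time) > np.timedelta64(0, "ns")):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.accel)):
            raise ValueError("acceleration values must be finite")
        if np.any(np.abs(self.accel) > MAX_ABS_G):
            raise ValueError(f"acceleration exceeds +/-{MAX_ABS_G} g device range")

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]


@dataclass
class UniformRecording:
    """A recording interpolated onto uniform grids, split at long gaps.

    ``times`` holds each sample's offset in seconds from ``start_time``;
    within a segment the offsets are uniform at ``1/rate``.
    ``segment_breaks`` lists the sample index at which each segment after
    the first begins (a gap longer than ``max_gap`` was not interpolated
    across).
    """

    subject_id: str
    start_time: np.datetime64
    rate: float
    data: np.ndarray  # (n, 3) device-frame g
    times: np.ndarray  # (n,) seconds since start_time
    segment_breaks: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def segments(self) -> list[tuple[int, int]]:
        """Half-open ``[start, end)`` index ranges of the contiguous segments."""
        bounds = [0, *self.segment_breaks, self.n_samples]
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    def time_of(self, index: int) -> np.datetime64:
        """Wall-clock timestamp of a sample."""
        return self.start_time + np.timedelta64(
            int(round(self.times[index] * 1e9)), "ns"
        )


def read_accel_csv(source, subject_id: str) -> RawRecording:
    """Read an AX3-GUI-style CSV into a :class:`RawRecording`.

    ``source`` may be a path, a text stream, or a CSV string. A header line
    ``timestamp,ax,ay,az`` is optional. Malformed rows raise
    :class:`~gaitspeed.errors.ParseError` naming the 1-based data row.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(
        source,
        header=None,
        names=["timestamp", "ax", "ay", "az"],
        dtype=str,
        skipinitialspace=True,
        skip_blank_lines=True,
    )
    if len(df) and str(df.iloc[0, 0]).strip().lower() == "timestamp":
        df = df.iloc[1:].reset_index(drop=True)
    if len(df) < 2:
        raise EmptyInputError(f"need >= 2 data rows, got {len(df)}")

    t = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    if t.isna().any():
        row = int(t.isna().idxmax()) + 1
        raise ParseError(row, f"malformed timestamp {df['timestamp'].iloc[row - 1]!r}")
    accel = np.empty((len(df), 3))
    for j, col in enumerate(("ax", "ay", "az")):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 1
            raise ParseError(row, f"non-numeric {col} value {df[col].iloc[row - 1]!r}")
        # numpy's string conversion is correctly rounded, so repr-precision
        # values survive a write/read round trip bit-exactly
        accel[:, j] = df[col].to_numpy(dtype=float)
    return RawRecording(subject_id, t.to_numpy(), accel)


def write_accel_csv(rec: RawRecording, dest=None) -> str | None:
    """Write a recording in the dialect :func:`read_accel_csv` expects.

    Returns the CSV text when ``dest`` is ``None``, otherwise writes to the
    path or stream. Floats are written with ``repr`` precision so a
    write/read round trip preserves values exactly.
    """
    stamps = np.datetime_as_string(rec.time.astype("datetime64[us]"))
    lines = ["timestamp,ax,ay,az"]
    for ts, (ax, ay, az) in zip(stamps, rec.accel):
        lines.append(f"{ts},{float(ax)!r},{float(ay)!r},{float(az)!r}")
    text = "\n".join(lines) + "\n"
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w") as fh:
            fh.write(text)
    return None


def resample_uniform(
    rec: RawRecording, rate: float = 100.0, max_gap: float = 1.0
) -> UniformRecording:
    """Linearly interpolate a recording onto uniform per-segment grids.

    Any inter-sample gap longer than ``max_gap`` seconds is never
    interpolated across: the grid stops before the gap and restarts at the
    first sample after it, and the restart index is recorded in
    ``segment_breaks``. Already-uniform input at the same rate is returned
    value-identical.
    """
    if rate < MIN_RATE_HZ:
        raise ConfigError(f"rate must be >= {MIN_RATE_HZ} Hz, got {rate}")
    t = (rec.time - rec.time[0]) / np.timedelta64(1, "s")
    gap_after = np.where(np.diff(t) > max_gap)[0]
    seg_bounds = [0, *(gap_after + 1), len(t)]

    chunks, chunk_times, breaks = [], [], []
    n_out = 0
    for i in range(len(seg_bounds) - 1):
        lo, hi = seg_bounds[i], seg_bounds[i + 1]
        if hi - lo < 2:  # an isolated sample carries no interpolable signal
            continue
        t0, t1 = t[lo], t[hi - 1]
        grid = t0 + np.arange(int(np.floor((t1 - t0) * rate + 1e-9)) + 1) / rate
        seg = np.column_stack(
            [np.interp(grid, t[lo:hi], rec.accel[lo:hi, j]) for j in range(3)]
        )
        if n_out > 0:
            breaks.append(n_out)
        chunks.append(seg)
        chunk_times.append(grid)
        n_out += len(grid)
    if not chunks:
        raise EmptyInputError("no segment with >= 2 samples after gap splitting")
    return UniformRecording(
        subject_id=rec.subject_id,
        start_time=rec.time[0],
        rate=float(rate),
        data=np.vstack(chunks),
        times=np.concatenate(chunk_times),
        segment_breaks=breaks,
    )
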