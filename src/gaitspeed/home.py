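"""Free-living sustained-walk detection and per-subject home summaries.

A *sustained walk* is a detected walking bout whose estimated distance
(predicted speed x duration) reaches 7.62 m — the 25-foot distance of the
clinic T25FW test — and whose start falls inside daytime hours. The two
headline home metrics are the maximum sustained walking speed over the
whole observation period and the mean speed over all sustained walks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import WalkBout

#: The ">25 feet" sustained-walk distance gate, metres.
SUSTAINED_DISTANCE_M = 7.62

#: Default daytime window (local hours, half-open).
DAYTIME = (7, 22)


@dataclass(frozen=True)
class TimedBout:
    """A walking bout with its wall-clock start and predicted speed."""

    bout: WalkBout
    start_time: np.datetime64
    speed: float  # m/s, from predict_bout_speed


@dataclass(frozen=True)
class SustainedWalk:
    """A bout that passed the distance and daytime gates."""

    bout: WalkBout
    start_time: np.datetime64
    speed: float

    @property
    def est_distance(self) -> float:
        return self.speed * self.bout.duration


@dataclass
class HomeSummary:
    """Per-subject summary of sustained home walking."""

    subject_id: str
    n_sustained: int
    max_speed: float  # nan when n_sustained == 0
    mean_speed: float  # nan when n_sustained == 0
    per_day: pd.DataFrame  # date, n_sustained, max_speed, mean_speed


def _hour_of(ts: np.datetime64) -> float:
    day = ts.astype("datetime64[D]")
    return (ts - day) / np.timedelta64(1, "h")


def find_sustained_walks(
    bouts_with_speeds: list[TimedBout],
    daytime_window: tuple[float, float] = DAYTIME,
) -> list[SustainedWalk]:
    """Keep bouts covering >= 7.62 m that start inside the daytime window."""
    lo, hi = daytime_window
    out = []
    for tb in bouts_with_speeds:
        if tb.speed * tb.bout.duration < SUSTAINED_DISTANCE_M:
            continue
        if not lo <= _hour_of(tb.start_time) < hi:
            continue
        out.append(SustainedWalk(tb.bout, tb.start_time, tb.speed))
    return out


def summarize_home(walks: list[SustainedWalk], subject_id: str) -> HomeSummary:
    """Max and mean sustained speed overall, plus a per-calendar-day table."""
    if not walks:
        return HomeSummary(
            subject_id,
            0,
            float("nan"),
            float("nan"),
            pd.DataFrame(columns=["date", "n_sustained", "max_speed", "mean_speed"]),
        )
    speeds = np.array([w.speed for w in walks])
    dates = [str(w.start_time.astype("datetime64[D]")) for w in walks]
    per_day = (
        pd.DataFrame({"date": dates, "speed": speeds})
        .groupby("date")["speed"]
        .agg(n_sustained="size", max_speed="max", mean_speed="mean")
        .reset_index()
    )
    return HomeSummary(
        subject_id,
        len(walks),
        float(speeds.max()),
        float(speeds.mean()),
        per_day,
    )
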