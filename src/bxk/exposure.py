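"""Blast exposure histories and the dose drive they impose.

A weapons-training schedule (days, daily average blast overpressure,
shots fired) is converted into an ordered timeline of blast events.
Each event contributes a residual-damage level ``lambda``: zero below
the non-dimensional injury threshold (full recovery), linear in the
overpressure exceedance above it (chronic damage proportional to BOP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import DoseConfig


class InputError(ValueError):
    """Invalid user-supplied exposure data."""


@dataclass(frozen=True)
class BlastEvent:
    """A single blast exposure on the study clock."""

    time: float  # h
    overpressure: float  # peak BOP, psi
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise InputError(f"event time must be finite, got {self.time}")
        if self.overpressure < 0:
            raise InputError(f"overpressure must be >= 0, got {self.overpressure}")


@dataclass(frozen=True)
class ExposureTimeline:
    """Strictly time-ordered blast events for one subject."""

    events: tuple[BlastEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InputError("events must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


@dataclass(frozen=True)
class TrainingSchedule:
    """A multi-day weapons-training design.

    Defaults reflect a three-day 0.50-caliber rifle course: 6 h of
    training per day, serum drawn on average 2.48 h before training and
    1.40 h after it ends.
    """

    n_days: int
    daily_bop: tuple[float, ...]  # psi, one per day
    shots_per_day: tuple[int, ...] | None = None
    training_start_hour: float = 9.0
    training_duration: float = 6.0  # h
    pre_draw_offset: float = 2.48  # h before training start
    post_draw_offset: float = 1.40  # h after training end
    day_length: float = 24.0  # h

    def __post_init__(self) -> None:
        if self.n_days < 0:
            raise InputError("n_days must be >= 0")
        if len(self.daily_bop) != self.n_days:
            raise InputError(
                f"daily_bop has {len(self.daily_bop)} entries for n_days={self.n_days}"
            )
        if self.training_duration <= 0:
            raise InputError("training_duration must be > 0")
        if self.pre_draw_offset <= 0 or self.post_draw_offset <= 0:
            raise InputError("draw offsets must be > 0")
        if self.shots_per_day is not None:
            if len(self.shots_per_day) != self.n_days:
                raise InputError("shots_per_day length must equal n_days")
            if any(s < 0 for s in self.shots_per_day):
                raise InputError("shot counts must be >= 0")
        if any(b < 0 for b in self.daily_bop):
            raise InputError("daily BOP values must be >= 0")

    def day_start(self, day: int) -> float:
        """Study-clock hour at which training begins on ``day`` (0-based)."""
        return day * self.day_length + self.training_start_hour

    def day_end(self, day: int) -> float:
        return self.day_start(day) + self.training_duration


def residual_damage(bop: float, params: DoseConfig) -> float:
    """Residual damage level left by a blast of peak overpressure ``bop``.

    Zero at or below the injury threshold (full recovery); above it,
    ``lambda_gain * (bop - threshold)`` — continuous, piecewise linear,
    non-decreasing in the overpressure.
    """
    if bop < 0:
        raise InputError(f"overpressure must be >= 0, got {bop}")
    return params.lambda_gain * max(0.0, bop - params.threshold)


def build_timeline(
    schedule: TrainingSchedule, mode: str = "daily_aggregate"
) -> ExposureTimeline:
    """Convert a training schedule into a blast-event timeline.

    ``daily_aggregate`` places one event per training day at the
    midpoint of the 6-h window carrying that day's average BOP (the
    experimental dataset reports daily averages).  ``per_shot`` spreads
    ``shots_per_day`` events uniformly across each window, each at the
    day's average BOP, for sensitivity studies.
    """
    events: list[BlastEvent] = []
    if mode == "daily_aggregate":
        for day in range(schedule.n_days):
            mid = schedule.day_start(day) + schedule.training_duration / 2.0
            events.append(BlastEvent(mid, schedule.daily_bop[day], f"day{day + 1}"))
    elif mode == "per_shot":
        if schedule.shots_per_day is None:
            raise InputError("per_shot mode requires shots_per_day")
        for day in range(schedule.n_days):
            n = schedule.shots_per_day[day]
            if n == 0:
                continue
            spacing = schedule.training_duration / n
            start = schedule.day_start(day)
            for k in range(n):
                # shots centered in equal sub-intervals of the window
                t = start + (k + 0.5) * spacing
                events.append(
                    BlastEvent(t, schedule.daily_bop[day], f"day{day + 1}_shot{k + 1}")
                )
    else:
        raise InputError(f"unknown timeline mode {mode!r}")
    return ExposureTimeline(tuple(events))


def lambda_profile(timeline: ExposureTimeline, params: DoseConfig) -> list[tuple[float, float]]:
    """Piecewise-constant residual damage in effect after each event.

    The level in force at time t is the maximum residual damage over
    all events at or before t (chronic damage does not resolve within
    the study window).  Returns (event_time, lambda_in_effect) pairs.
    """
    out: list[tuple[float, float]] = []
    current = 0.0
    for ev in timeline:
        current = max(current, residual_damage(ev.overpressure, params))
        out.append((ev.time, current))
    return out
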