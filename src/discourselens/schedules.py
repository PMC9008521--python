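"""Time-varying probability schedules for the stream simulator.

A schedule maps a calendar date to a value in [0, 1] (a prevalence or a
retweet probability).  Three shapes cover the phenomena the simulator
plants: a constant, a log-linear ramp (geometric growth, used for topic
prevalence rising over orders of magnitude) and a logistic transition
(used for the retweet probability tipping through 0.5).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


@dataclass(frozen=True)
class ConstantSchedule:
    value: float

    def __call__(self, date: dt.date) -> float:
        return float(self.value)

    def to_dict(self) -> dict:
        return {"kind": "constant", "value": self.value}


@dataclass(frozen=True)
class LogLinearSchedule:
    """Geometric interpolation from ``start_value`` at ``start_date`` to
    ``end_value`` at ``end_date``; clamped outside the interval."""

    start_date: dt.date
    end_date: dt.date
    start_value: float
    end_value: float

    def __post_init__(self):
        if self.start_value <= 0 or self.end_value <= 0:
            raise ValueError("log-linear schedule needs positive endpoints")
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")

    def __call__(self, date: dt.date) -> float:
        span = (self.end_date - self.start_date).days
        t = (date - self.start_date).days / span
        t = min(1.0, max(0.0, t))
        return math.exp(
            (1 - t) * math.log(self.start_value) + t * math.log(self.end_value)
        )

    def to_dict(self) -> dict:
        return {
            "kind": "log_linear",
            "start_date": self.start_date.isoformat(),
            "end_date": self.end_date.isoformat(),
            "start_value": self.start_value,
            "end_value": self.end_value,
        }


@dataclass(frozen=True)
class LogisticSchedule:
    """Sigmoid rise from ``low`` to ``high`` centred on ``midpoint``.

    ``scale_days`` is the logistic scale parameter; ~90% of the transition
    happens within +-3 scales of the midpoint.
    """

    low: float
    high: float
    midpoint: dt.date
    scale_days: float

    def __post_init__(self):
        if self.scale_days <= 0:
            raise ValueError("scale_days must be positive")

    def __call__(self, date: dt.date) -> float:
        x = (date - self.midpoint).days / self.scale_days
        return self.low + (self.high - self.low) / (1.0 + math.exp(-x))

    def to_dict(self) -> dict:
        return {
            "kind": "logistic",
            "low": self.low,
            "high": self.high,
            "midpoint": self.midpoint.isoformat(),
            "scale_days": self.scale_days,
        }


def schedule_from_dict(obj) -> "Schedule":
    """Build a schedule from a plain dict (YAML-friendly) or pass through
    anything already callable."""
    if callable(obj):
        return obj
    if isinstance(obj, (int, float)):
        return ConstantSchedule(float(obj))
    kind = obj["kind"]
    if kind == "constant":
        return ConstantSchedule(float(obj["value"]))
    if kind == "log_linear":
        return LogLinearSchedule(
            _as_date(obj["start_date"]),
            _as_date(obj["end_date"]),
            float(obj["start_value"]),
            float(obj["end_value"]),
        )
    if kind == "logistic":
        return LogisticSchedule(
            float(obj["low"]),
            float(obj["high"]),
            _as_date(obj["midpoint"]),
            float(obj["scale_days"]),
        )
    raise ValueError(f"unknown schedule kind: {kind!r}")


Schedule = ConstantSchedule | LogLinearSchedule | LogisticSchedule
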