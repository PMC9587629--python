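"""QALY losses from waiting time and from excess 30-day events.

Two mechanisms, both small per patient:

* Waiting: the hours spent under assessment are weighted by an annualised
  utility decrement, so a 22.3-h hospital stay costs
  ``22.3 / 8766 × 0.232 ≈ 0.00059`` QALYs.
* Missed/extra events: each excess 30-day AMI or death costs the
  discounted lifetime QALY difference between an average 56-year-old
  without and with an index event.  The base case sets this to zero in
  both arms (observed event rates are below the accepted miss-rate
  ceiling); the conservative scenario charges each arm its observed rate.

Losses are carried unrounded; five-decimal rounding is applied only at
report rendering.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

from ._rounding import round_qaly
from .params import ModelParameters, ScenarioSpec

__all__ = ["QalyLoss", "los_qaly_loss", "event_qaly_loss", "strategy_qaly"]

Setting = Literal["primary_care", "hospital"]


@dataclasses.dataclass(frozen=True)
class QalyLoss:
    """Per-patient QALY loss, decomposed; components are ≤ 0."""

    los_component: float
    event_component: float

    @property
    def total(self) -> float:
        return self.los_component + self.event_component

    @property
    def total_printed(self) -> float:
        """Sum of five-decimal rounded components (report convention)."""
        return round_qaly(round_qaly(self.los_component)
                          + round_qaly(self.event_component))


def los_qaly_loss(los_hours: float, decrement: float,
                  hours_per_year: float = 8766.0) -> float:
    """QALYs lost to time spent waiting under assessment (≤ 0)."""
    if los_hours < 0:
        raise ValueError("length of stay must be non-negative")
    if not 0.0 <= decrement <= 1.0:
        raise ValueError("utility decrement must lie in [0, 1]")
    return -(los_hours / hours_per_year) * decrement


def event_qaly_loss(event_rate: float, qaly_loss_per_event: float) -> float:
    """Expected QALYs lost to 30-day AMI/death events (≤ 0)."""
    if not 0.0 <= event_rate <= 1.0:
        raise ValueError("event rate must lie in [0, 1]")
    if qaly_loss_per_event < 0:
        raise ValueError("per-event QALY loss must be non-negative")
    return -event_rate * qaly_loss_per_event


def strategy_qaly(scenario: ScenarioSpec, setting: Setting,
                  params: ModelParameters) -> QalyLoss:
    """Combined per-patient QALY loss for one arm under one scenario."""
    u, t, e = params.utility, params.time, params.events
    if setting == "primary_care":
        los_h = scenario.los_primary_mean_h
        rate = e.rate_primary_30d
    elif setting == "hospital":
        los_h = t.los_hospital_mean_h
        rate = e.rate_hospital_30d
    else:
        raise ValueError(f"unknown setting {setting!r}")
    los = los_qaly_loss(los_h, u.waiting_utility_decrement, t.hours_per_year)
    if scenario.include_excess_events:
        event = event_qaly_loss(rate, u.qaly_loss_per_event)
    else:
        event = 0.0
    return QalyLoss(los_component=los, event_component=event)
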