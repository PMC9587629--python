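"""Incremental cost-effectiveness analysis of the two strategies.

Sign conventions: differences are primary-care arm minus hospital arm;
QALY differences are computed on losses, so a positive ΔQALY is a health
gain for the primary-care strategy.  Quadrants on the cost-effectiveness
plane:

* ``dominant``  — cheaper and more effective (no ICER is reported);
* ``dominated`` — dearer and less effective;
* ``ne_trade``  — dearer but more effective: cost-effective iff
  ICER ≤ threshold;
* ``sw_trade``  — cheaper but less effective: cost-effective iff the
  savings per QALY lost are at least the threshold (ICER ≥ λ), i.e. the
  money freed buys more health elsewhere than is lost here.

Boundary ICERs equal to the threshold count as cost-effective.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Literal

from ._rounding import round_half_up
from .costing import StrategyCost
from .qaly import QalyLoss

__all__ = [
    "Quadrant",
    "StrategyOutcome",
    "IncrementalResult",
    "incremental",
    "icer",
    "icer_at_printed_precision",
    "verdict",
    "net_monetary_benefit",
]


class Quadrant(str, enum.Enum):
    dominant = "dominant"
    dominated = "dominated"
    ne_trade = "ne_trade"
    sw_trade = "sw_trade"
    indifferent = "indifferent"   # ΔQALY = 0 boundary: cost-only comparison


@dataclasses.dataclass(frozen=True)
class StrategyOutcome:
    """Per-strategy expected cost, QALY loss and mean LOS, with breakdowns."""

    strategy: str
    scenario: str
    cost: StrategyCost
    qaly: QalyLoss
    mean_los_h: float


@dataclasses.dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_qaly: float
    quadrant: Quadrant
    icer: float | None
    scenario: str = ""

    def nmb(self, lam: float) -> float:
        return net_monetary_benefit(self.delta_cost, self.delta_qaly, lam)


def incremental(primary: StrategyOutcome,
                hospital: StrategyOutcome) -> tuple[float, float]:
    """(ΔCost, ΔQALY), primary-care minus hospital, under one scenario."""
    if primary.scenario != hospital.scenario:
        raise ValueError(
            f"scenario mismatch: {primary.scenario!r} vs {hospital.scenario!r}")
    delta_cost = primary.cost.total - hospital.cost.total
    delta_qaly = primary.qaly.total - hospital.qaly.total
    return float(delta_cost), float(delta_qaly)


def classify(delta_cost: float, delta_qaly: float) -> Quadrant:
    if delta_qaly == 0:
        return Quadrant.indifferent
    if delta_cost <= 0 and delta_qaly > 0:
        return Quadrant.dominant
    if delta_cost > 0 and delta_qaly < 0:
        return Quadrant.dominated
    if delta_cost > 0:
        return Quadrant.ne_trade
    return Quadrant.sw_trade


def icer(delta_cost: float, delta_qaly: float,
         scenario: str = "") -> IncrementalResult:
    """Classify the quadrant; report a cost-per-QALY ratio only where one
    is meaningful (the two trade-off quadrants)."""
    quadrant = classify(delta_cost, delta_qaly)
    ratio = (delta_cost / delta_qaly
             if quadrant in (Quadrant.ne_trade, Quadrant.sw_trade) else None)
    return IncrementalResult(delta_cost=delta_cost, delta_qaly=delta_qaly,
                             quadrant=quadrant, icer=ratio, scenario=scenario)


def icer_at_printed_precision(delta_cost: float, delta_qaly: float,
                              qaly_decimals: int = 4,
                              scenario: str = "") -> IncrementalResult:
    """ICER computed from the report-precision pair.

    Reports quote ΔQALY at four decimals (e.g. −0.0019) and whole-EUR
    ΔCost; the quoted ratio (EUR 880,000/QALY in the conservative
    scenario) follows from the quoted pair, not the unrounded one.
    """
    return icer(round_half_up(delta_cost, 0),
                round_half_up(delta_qaly, qaly_decimals), scenario=scenario)


def net_monetary_benefit(delta_cost: float, delta_qaly: float,
                         lam: float) -> float:
    """λ·ΔQALY − ΔCost at willingness-to-pay λ (EUR/QALY)."""
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return lam * delta_qaly - delta_cost


Verdict = Literal["cost_effective", "not_cost_effective", "dominant"]


def verdict(result: IncrementalResult, threshold: float) -> Verdict:
    """Decision at a single willingness-to-pay threshold (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    q = result.quadrant
    if q is Quadrant.dominant:
        return "dominant"
    if q is Quadrant.dominated:
        return "not_cost_effective"
    if q is Quadrant.indifferent:
        return "cost_effective" if result.delta_cost <= 0 else "not_cost_effective"
    if q is Quadrant.ne_trade:
        return ("cost_effective" if result.icer <= threshold
                else "not_cost_effective")
    return ("cost_effective" if result.icer >= threshold
            else "not_cost_effective")


def verdict_band(result: IncrementalResult,
                 band: tuple[float, float]) -> dict[str, Verdict]:
    """Verdicts at both ends of a threshold band."""
    lo, hi = band
    if lo > hi:
        raise ValueError("band must be ordered (low, high)")
    return {"at_low": verdict(result, lo), "at_high": verdict(result, hi)}
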