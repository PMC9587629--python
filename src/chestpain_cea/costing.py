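"""Expected per-patient cost of each triage strategy.

The decision tree has two arms for a low-risk chest-pain patient presenting
to emergency primary care:

* ``primary_care_algorithm`` — assessed on site with the 0/1-h hs-cTnT
  algorithm: shared EMS-to-clinic and consultation costs plus the
  algorithm add-on (laboratory, personnel, outpatient referral).
* ``hospital_standard`` — the same shared components plus an ambulance
  transfer to hospital (probability by scenario) and the mean DRG cost of
  a low-risk admission.

Costs are computed top-down from the tree (reproducing the study's summary
table) and bottom-up from patient-level records as a Monte-Carlo
cross-check.  Components are rounded to whole EUR *before* totalling —
the printed totals are sums of printed rounded components — while
unrounded values are retained on each component.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal, Mapping

import pandas as pd

from ._rounding import round_eur
from .params import ModelParameters, ScenarioSpec

__all__ = [
    "CostComponent",
    "StrategyCost",
    "expected_ambulance_cost",
    "primary_addon_cost",
    "drg_mean_cost",
    "strategy_total_cost",
    "cost_from_records",
]

Strategy = Literal["primary_care_algorithm", "hospital_standard"]

#: Components present in both arms; they cancel exactly in the incremental
#: cost and the table prints them as "assumed similar".
SHARED_COMPONENTS = ("ems_to_primary", "consultation")


@dataclasses.dataclass(frozen=True)
class CostComponent:
    label: str
    unit_cost: float
    probability_applied: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability_applied <= 1.0:
            raise ValueError(
                f"probability for {self.label!r} outside [0, 1]: "
                f"{self.probability_applied}")
        if self.unit_cost < 0:
            raise ValueError(f"negative unit cost for {self.label!r}")

    @property
    def expected_cost(self) -> float:
        return self.probability_applied * self.unit_cost

    @property
    def expected_cost_eur(self) -> int:
        return round_eur(self.expected_cost)


@dataclasses.dataclass(frozen=True)
class StrategyCost:
    strategy: Strategy
    scenario: str
    components: tuple[CostComponent, ...]

    @property
    def total(self) -> int:
        """Whole-EUR total: sum of per-component rounded expected costs."""
        return sum(c.expected_cost_eur for c in self.components)

    @property
    def total_unrounded(self) -> float:
        return sum(c.expected_cost for c in self.components)

    def component(self, label: str) -> CostComponent:
        for c in self.components:
            if c.label == label:
                return c
        raise KeyError(label)


def expected_ambulance_cost(p: float, unit_cost: float) -> float:
    """Expected EMS transport cost: probability of transport × unit cost."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"transport probability outside [0, 1]: {p}")
    if unit_cost < 0:
        raise ValueError("negative transport unit cost")
    return p * unit_cost


def primary_addon_cost(scenario: ScenarioSpec,
                       params: ModelParameters) -> dict[str, float]:
    """Per-patient add-on of running the 0/1-h algorithm in primary care.

    Returns the breakdown: laboratory/diagnostics, personnel (wage- or
    tariff-costed by scenario), and increased outpatient cardiac referral,
    plus their sum under ``"total"``.
    """
    c = params.costs
    breakdown = {
        "diagnostics": c.algorithm_lab_cost,
        "personnel": scenario.personnel_cost,
        "outpatient_referral": c.outpatient_referral_cost,
    }
    breakdown["total"] = sum(breakdown.values())
    return breakdown


def drg_mean_cost(total: float, n: int) -> float:
    """Mean DRG-based cost per low-risk hospital admission."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    if total < 0:
        raise ValueError("negative DRG total")
    return total / n


def strategy_total_cost(scenario: ScenarioSpec, strategy: Strategy,
                        params: ModelParameters) -> StrategyCost:
    """Top-down expected cost of one strategy under one scenario."""
    c = params.costs
    shared = (
        CostComponent("ems_to_primary", c.ems_cost_per_transport,
                      c.p_ambulance_to_primary),
        CostComponent("consultation", c.consultation_cost),
    )
    if strategy == "primary_care_algorithm":
        addon = primary_addon_cost(scenario, params)["total"]
        components = shared + (CostComponent("algorithm_addon", addon),)
    elif strategy == "hospital_standard":
        components = shared + (
            CostComponent("ems_to_hospital", c.ems_cost_per_transport,
                          scenario.p_ambulance_to_hospital),
            CostComponent("hospital_drg",
                          drg_mean_cost(c.drg_total, c.n_hospital_cohort)),
        )
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return StrategyCost(strategy=strategy, scenario=scenario.name.value,
                        components=components)


@dataclasses.dataclass(frozen=True)
class RecordCostSummary:
    n: int
    mean_cost: float | None
    se: float | None
    component_means: Mapping[str, float]

    @property
    def empty(self) -> bool:
        return self.n == 0


_REQUIRED_TARIFFS = ("ems_transport", "consultation", "algorithm_addon")


def cost_from_records(records: pd.DataFrame,
                      tariffs: Mapping[str, float]) -> RecordCostSummary:
    """Bottom-up mean per-patient cost from patient-level records.

    Per record: ambulance use × EMS tariff + consultation + either the
    algorithm add-on (primary-care records) or the record's own hospital
    cost.  On large synthetic cohorts this agrees with the analytic tree
    within Monte-Carlo error.
    """
    for key in _REQUIRED_TARIFFS:
        if key not in tariffs:
            raise KeyError(f"tariff map missing key {key!r}")
    if records.empty:
        return RecordCostSummary(0, None, None, {})
    settings = set(records["setting"].unique())
    if len(settings) > 1:
        raise ValueError(f"records mix settings: {sorted(settings)}")
    ambulance = (records["ambulance"].astype(float)
                 if "ambulance" in records else 0.0 * records["los_hours"])
    ems = ambulance * tariffs["ems_transport"]
    consult = pd.Series(tariffs["consultation"], index=records.index)
    if settings == {"hospital"}:
        stay = records["cost_eur"].astype(float)
        stay_label = "hospital_drg"
        if stay.isna().any():
            raise ValueError("hospital records missing cost_eur")
    else:
        stay = pd.Series(tariffs["algorithm_addon"], index=records.index,
                         dtype=float)
        stay_label = "algorithm_addon"
    per_record = ems + consult + stay
    n = len(per_record)
    se = per_record.std(ddof=1) / n**0.5 if n > 1 else None
    return RecordCostSummary(
        n=n, mean_cost=float(per_record.mean()), se=se,
        component_means={"ems": float(ems.mean()),
                         "consultation": float(consult.mean()),
                         stay_label: float(stay.mean())},
    )


def incremental_cost(primary: StrategyCost, hospital: StrategyCost) -> int:
    """Whole-EUR cost difference, primary-care arm minus hospital arm."""
    return primary.total - hospital.total


def components_frame(costs: Iterable[StrategyCost]) -> pd.DataFrame:
    """Long-format component table (one row per strategy × component)."""
    rows = [
        {"scenario": sc.scenario, "strategy": sc.strategy,
         "component": c.label, "unit_cost": c.unit_cost,
         "probability": c.probability_applied,
         "expected_cost": c.expected_cost,
         "expected_cost_eur": c.expected_cost_eur}
        for sc in costs for c in sc.components
    ]
    return pd.DataFrame(rows)
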