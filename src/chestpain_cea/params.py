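"""Model parameters, micro-costing conversion rules, and scenario resolution.

Every quantity used anywhere downstream lives here exactly once (single-home
rule).  Monetary values are 2020 EUR; the configured NOK→EUR exchange rate
(10.73) and the Norwegian micro-costing gross-up rules (payroll ×1.3, HELFO
reimbursement ×2) are applied through :func:`convert_currency` and
:func:`gross_up` rather than baked into derived constants.

Two analysis scenarios exist: a *base case* (most-likely inputs) and a
*conservative* scenario that takes a deliberate worst case for the
primary-care strategy on four inputs — personnel costed by tariff instead of
wage, an assumed excess 30-day event rate, a lower ambulance-to-hospital
probability, and the upper range of the primary-care length of stay.
"""

from __future__ import annotations

import enum
from typing import Any, Literal, Mapping

import pydantic
import yaml
from pydantic import BaseModel, Field

__all__ = [
    "ConfigError",
    "CostParameters",
    "TimeParameters",
    "UtilityParameters",
    "EventRateParameters",
    "EconomicSettings",
    "MarkovSettings",
    "ModelParameters",
    "ScenarioName",
    "ScenarioSpec",
    "load_parameters",
    "resolve_scenario",
    "gross_up",
    "convert_currency",
]


class ConfigError(ValueError):
    """Raised for unreadable, unknown-key, or out-of-range configuration."""


class _Section(BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid", frozen=True)


class CostParameters(_Section):
    """Unit costs and transport probabilities (2020 EUR)."""

    ems_cost_per_transport: float = Field(559.0, ge=0)
    p_ambulance_to_primary: float = Field(0.29, ge=0, le=1)
    p_ambulance_to_hospital_base: float = Field(0.90, ge=0, le=1)
    p_ambulance_to_hospital_conservative: float = Field(0.75, ge=0, le=1)
    consultation_cost: float = Field(166.0, ge=0)
    algorithm_lab_cost: float = Field(41.0, ge=0)
    personnel_cost_wage: float = Field(99.0, ge=0)
    personnel_cost_tariff: float = Field(137.0, ge=0)
    outpatient_referral_cost: float = Field(52.0, ge=0)
    drg_total: float = Field(840_664.0, ge=0)
    n_hospital_cohort: int = Field(567, gt=0)
    nok_per_eur: float = Field(10.73, gt=0)
    payroll_multiplier: float = Field(1.3, ge=1)
    helfo_multiplier: float = Field(2.0, ge=1)


class TimeParameters(_Section):
    """Length-of-stay moments (hours) and the hours-per-year convention."""

    los_primary_base_mean_h: float = Field(3.4, gt=0)
    los_primary_base_sd_h: float = Field(0.740, ge=0)
    los_primary_conservative_mean_h: float = Field(4.0, gt=0)
    los_primary_conservative_sd_h: float = Field(0.870, ge=0)
    los_hospital_mean_h: float = Field(22.3, gt=0)
    los_hospital_sd_h: float = Field(22.010, ge=0)
    hours_per_year: float = Field(8766.0, gt=0)  # 365.25 * 24


class UtilityParameters(_Section):
    """Health-related quality-of-life inputs for the QALY model.

    ``waiting_utility_decrement`` is the annualised utility lost while
    waiting for rule-out (applied pro rata to the length of stay);
    ``qaly_loss_per_event`` is the discounted lifetime QALY difference
    between an average 56-year-old without and with an index AMI
    (13.3 − 11.1 at printed rounding).
    """

    waiting_utility_decrement: float = Field(0.232, ge=0, le=1)
    qaly_loss_per_event: float = Field(2.222, ge=0)
    remaining_qalys_no_event: float = Field(13.3, gt=0)
    remaining_qalys_post_ami: float = Field(11.1, gt=0)
    utility_non_cvd: float = Field(0.85, ge=0, le=1)
    utility_cvd: float = Field(0.74, ge=0, le=1)


class EventRateParameters(_Section):
    """Observed 30-day AMI/death rates among non-hospitalised low-risk patients."""

    rate_primary_30d: float = Field(5 / 1485, ge=0, le=1)
    rate_hospital_30d: float = Field(2 / 862, ge=0, le=1)
    excess_rate_conservative: float = Field(0.001, ge=0, le=1)
    base_case_event_loss_zero: bool = True


class EconomicSettings(_Section):
    discount_rate: float = Field(0.04, ge=0)
    threshold_low: float = Field(25_600.0, ge=0)
    threshold_high: float = Field(76_900.0, ge=0)
    reference_year: int = 2020

    @pydantic.model_validator(mode="after")
    def _band_ordered(self) -> "EconomicSettings":
        if self.threshold_low > self.threshold_high:
            raise ValueError("threshold_low must not exceed threshold_high")
        return self


class MarkovSettings(_Section):
    """Long-term three-state cohort model inputs.

    Background mortality follows a Gompertz schedule
    ``q(a) = 1 - exp(-b * exp(theta * a))``; CVD carries a mortality hazard
    ratio applied on the survival scale.  ``mortality_scale`` and
    ``utility_scale`` are the two calibration knobs used to hit the
    remaining-QALY anchors (13.3 / 11.1 at age 56).
    """

    start_age: int = Field(56, ge=0)
    max_age: int = Field(110, gt=0)
    gompertz_b: float = Field(2.0e-5, gt=0)
    gompertz_theta: float = Field(0.095, gt=0)
    hr_cvd_mortality: float = Field(1.6, ge=0)
    annual_cvd_incidence: float = Field(0.01, ge=0, le=1)
    mortality_scale: float = Field(1.0, gt=0)
    utility_scale: float = Field(1.0, gt=0)
    alive_tolerance: float = Field(1e-6, gt=0)
    # Discounting exponent for the first (half-cycle-corrected) cycle.
    first_cycle_exponent: int = Field(1, ge=0)


class ModelParameters(_Section):
    """The full validated parameter set, with per-field provenance labels."""

    costs: CostParameters = CostParameters()
    time: TimeParameters = TimeParameters()
    utility: UtilityParameters = UtilityParameters()
    events: EventRateParameters = EventRateParameters()
    economics: EconomicSettings = EconomicSettings()
    markov: MarkovSettings = MarkovSettings()
    # Overuse of testing once the assay is available in primary care
    # (range 0.10-0.15); stored for sensitivity use only — those patients
    # are already counted in the primary-care cohort, so base outputs
    # exclude it.
    induced_testing_fraction: float = Field(0.15, ge=0, le=1)

    provenance: dict = Field(default_factory=dict, exclude=True)


# Fields whose defaults are printed study values, as opposed to package
# design choices ("default") or user overrides ("user").
_PAPER_FIELDS = {
    "costs": {
        "ems_cost_per_transport", "p_ambulance_to_primary",
        "p_ambulance_to_hospital_base", "p_ambulance_to_hospital_conservative",
        "consultation_cost", "algorithm_lab_cost", "personnel_cost_wage",
        "personnel_cost_tariff", "outpatient_referral_cost", "drg_total",
        "n_hospital_cohort", "nok_per_eur", "payroll_multiplier",
        "helfo_multiplier",
    },
    "time": {
        "los_primary_base_mean_h", "los_primary_base_sd_h",
        "los_primary_conservative_mean_h", "los_primary_conservative_sd_h",
        "los_hospital_mean_h", "los_hospital_sd_h",
    },
    "utility": {"remaining_qalys_no_event", "remaining_qalys_post_ami"},
    "events": {"rate_primary_30d", "rate_hospital_30d",
               "excess_rate_conservative"},
    "economics": {"discount_rate", "threshold_low", "threshold_high",
                  "reference_year"},
    "markov": {"start_age", "hr_cvd_mortality"},
}


def _provenance(user_config: Mapping[str, Any]) -> dict:
    labels: dict[str, str] = {}
    for section_name, section_cls in ModelParameters.model_fields.items():
        ann = section_cls.annotation
        if not (isinstance(ann, type) and issubclass(ann, BaseModel)):
            continue
        user_section = user_config.get(section_name, {}) or {}
        for field in ann.model_fields:
            key = f"{section_name}.{field}"
            if field in user_section:
                labels[key] = "user"
            elif field in _PAPER_FIELDS.get(section_name, set()):
                labels[key] = "paper"
            else:
                labels[key] = "default"
    labels["induced_testing_fraction"] = (
        "user" if "induced_testing_fraction" in user_config else "default"
    )
    return labels


def load_parameters(config_source: str | Mapping[str, Any] | None = None,
                    ) -> ModelParameters:
    """Build a validated :class:`ModelParameters` set.

    Parameters
    ----------
    config_source
        ``None`` for the full default set; a path to a YAML file; or an
        already-parsed mapping.  Unknown keys are rejected; values outside
        their documented ranges raise :class:`ConfigError` naming the field.
    """
    if config_source is None:
        raw: Mapping[str, Any] = {}
    elif isinstance(config_source, Mapping):
        raw = config_source
    else:
        try:
            with open(config_source) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise ConfigError(f"cannot read config {config_source!r}: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigError("config root must be a mapping of sections")
    try:
        params = ModelParameters(**raw)
    except pydantic.ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>"
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration field(s): {fields}") from exc
    return params.model_copy(update={"provenance": _provenance(raw)})


class ScenarioName(str, enum.Enum):
    base_case = "base_case"
    conservative = "conservative"


class ScenarioSpec(_Section):
    """The four scenario-varied inputs, resolved, plus shared parameters."""

    name: ScenarioName
    personnel_costing: Literal["wage", "tariff"]
    personnel_cost: float
    include_excess_events: bool
    p_ambulance_to_hospital: float
    los_primary_mean_h: float
    los_primary_sd_h: float


def resolve_scenario(params: ModelParameters,
                     name: str | ScenarioName) -> ScenarioSpec:
    """Resolve ``base_case`` or ``conservative`` to concrete input values."""
    try:
        name = ScenarioName(name)
    except ValueError:
        valid = ", ".join(s.value for s in ScenarioName)
        raise ConfigError(f"unknown scenario {name!r}; valid names: {valid}")
    c, t = params.costs, params.time
    if name is ScenarioName.base_case:
        return ScenarioSpec(
            name=name, personnel_costing="wage",
            personnel_cost=c.personnel_cost_wage,
            include_excess_events=False,
            p_ambulance_to_hospital=c.p_ambulance_to_hospital_base,
            los_primary_mean_h=t.los_primary_base_mean_h,
            los_primary_sd_h=t.los_primary_base_sd_h,
        )
    return ScenarioSpec(
        name=name, personnel_costing="tariff",
        personnel_cost=c.personnel_cost_tariff,
        include_excess_events=True,
        p_ambulance_to_hospital=c.p_ambulance_to_hospital_conservative,
        los_primary_mean_h=t.los_primary_conservative_mean_h,
        los_primary_sd_h=t.los_primary_conservative_sd_h,
    )


def gross_up(amount: float, rule: Literal["payroll", "helfo"],
             params: ModelParameters | None = None) -> float:
    """Apply a Norwegian micro-costing gross-up.

    ``payroll`` multiplies an average wage by 1.3 to cover payroll taxes
    and social charges; ``helfo`` doubles a HELFO reimbursement to cover
    the other financing sources of primary-care services.
    """
    if amount < 0:
        raise ValueError("gross_up requires a non-negative amount")
    p = params if params is not None else ModelParameters()
    if rule == "payroll":
        return amount * p.costs.payroll_multiplier
    if rule == "helfo":
        return amount * p.costs.helfo_multiplier
    raise ValueError(f"unknown gross-up rule {rule!r}")


def convert_currency(amount_nok: float,
                     nok_per_eur: float = 10.73) -> float:
    """NOK → EUR at the 2020 reference rate (EUR 1.00 = NOK 10.73)."""
    return amount_nok / nok_per_eur


def convert_currency_inverse(amount_eur: float,
                             nok_per_eur: float = 10.73) -> float:
    """EUR → NOK; exact inverse of :func:`convert_currency`."""
    return amount_eur * nok_per_eur
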