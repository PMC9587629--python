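"""Three-state Markov cohort model for long-term QALY consequences.

States are ``non_cvd``, ``cvd`` and ``dead`` (absorbing); the cycle length
is one year and a half-cycle correction credits each cycle with the
average of its start- and end-of-cycle occupancy.  Background mortality
follows an age-indexed schedule q(a) (Gompertz by default); living with
CVD multiplies the mortality *hazard* by a ratio (default 1.6), applied on
the survival scale as ``1 - (1 - q)^hr`` so that probabilities stay in
[0, 1] even when q is near 1.

The model's job is to supply the discounted remaining QALYs of an average
56-year-old with and without an index AMI (anchored at 13.3 and 11.1);
because the underlying life-table and CVD-incidence inputs are not part of
the printed evidence, a two-parameter calibration (a mortality scale and a
utility scale) pins the model to those anchors.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
from scipy import optimize

from .params import MarkovSettings

__all__ = [
    "MarkovState",
    "TransitionSchedule",
    "MarkovTrace",
    "CalibrationError",
    "gompertz_mortality",
    "build_schedule",
    "run_cohort",
    "discounted_qalys",
    "remaining_qalys",
    "calibrate_schedules",
]


class MarkovState(enum.IntEnum):
    non_cvd = 0
    cvd = 1
    dead = 2


class CalibrationError(RuntimeError):
    pass


def gompertz_mortality(age: np.ndarray | float, b: float,
                       theta: float) -> np.ndarray:
    """Annual death probability q(a) = 1 − exp(−b·exp(θ·a))."""
    return 1.0 - np.exp(-b * np.exp(theta * np.asarray(age, dtype=float)))


@dataclasses.dataclass(frozen=True)
class TransitionSchedule:
    """Age-indexed annual transition probabilities from ``start_age``."""

    start_age: int
    annual_mortality: np.ndarray          # q(a), a = start_age + index
    annual_cvd_incidence: np.ndarray      # same indexing
    hr_cvd_mortality: float = 1.6

    def __post_init__(self) -> None:
        q = np.asarray(self.annual_mortality, dtype=float)
        inc = np.asarray(self.annual_cvd_incidence, dtype=float)
        if q.shape != inc.shape:
            raise ValueError("mortality and incidence schedules differ in length")
        if np.any((q < 0) | (q > 1)) or np.any((inc < 0) | (inc > 1)):
            raise ValueError("schedule probabilities must lie in [0, 1]")
        if self.hr_cvd_mortality < 0:
            raise ValueError("hazard ratio must be non-negative")
        object.__setattr__(self, "annual_mortality", q)
        object.__setattr__(self, "annual_cvd_incidence", inc)

    @property
    def horizon(self) -> int:
        return len(self.annual_mortality)

    def cvd_mortality(self) -> np.ndarray:
        """Mortality under the CVD hazard ratio, on the survival scale."""
        q = self.annual_mortality
        return np.clip(1.0 - (1.0 - q) ** self.hr_cvd_mortality, 0.0, 1.0)


def build_schedule(settings: MarkovSettings,
                   start_age: int | None = None) -> TransitionSchedule:
    """Gompertz schedule from ``start_age`` to ``settings.max_age``."""
    a0 = settings.start_age if start_age is None else start_age
    if a0 >= settings.max_age:
        raise ValueError("start age must be below max_age")
    ages = np.arange(a0, settings.max_age)
    q = gompertz_mortality(ages, settings.gompertz_b * settings.mortality_scale,
                           settings.gompertz_theta)
    inc = np.full_like(q, settings.annual_cvd_incidence)
    return TransitionSchedule(start_age=a0, annual_mortality=q,
                              annual_cvd_incidence=inc,
                              hr_cvd_mortality=settings.hr_cvd_mortality)


@dataclasses.dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle state occupancy, raw and half-cycle corrected.

    ``occupancy`` has ``horizon + 1`` rows (row 0 = the starting
    distribution); ``half_cycle_corrected_occupancy`` has ``horizon`` rows,
    row t being the average of occupancy rows t and t+1.
    """

    start_age: int
    occupancy: np.ndarray
    half_cycle_corrected_occupancy: np.ndarray

    @property
    def horizon(self) -> int:
        return self.half_cycle_corrected_occupancy.shape[0]

    @property
    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.horizon)

    def alive_fraction(self) -> np.ndarray:
        return self.occupancy[:, :2].sum(axis=1)


def run_cohort(schedule: TransitionSchedule,
               start_state: MarkovState | str = MarkovState.non_cvd,
               horizon: int | None = None) -> MarkovTrace:
    """Forward iteration of the cohort over ``horizon`` one-year cycles."""
    if isinstance(start_state, str):
        start_state = MarkovState[start_state]
    if horizon is None:
        horizon = schedule.horizon
    if horizon < 1:
        raise ValueError("horizon must be at least one cycle")
    if horizon > schedule.horizon:
        missing = list(range(schedule.start_age + schedule.horizon,
                             schedule.start_age + horizon))
        raise ValueError(
            f"schedule ends before the requested horizon; missing ages {missing}")
    q = schedule.annual_mortality
    qc = schedule.cvd_mortality()
    inc = schedule.annual_cvd_incidence
    occ = np.zeros((horizon + 1, 3))
    occ[0, int(start_state)] = 1.0
    for t in range(horizon):
        non, cvd, dead = occ[t]
        surv_non = non * (1.0 - q[t])
        occ[t + 1, 0] = surv_non * (1.0 - inc[t])
        occ[t + 1, 1] = surv_non * inc[t] + cvd * (1.0 - qc[t])
        occ[t + 1, 2] = dead + non * q[t] + cvd * qc[t]
    corrected = 0.5 * (occ[:-1] + occ[1:])
    return MarkovTrace(start_age=schedule.start_age, occupancy=occ,
                       half_cycle_corrected_occupancy=corrected)


def discounted_qalys(trace: MarkovTrace,
                     state_utilities: Sequence[float],
                     discount_rate: float,
                     first_cycle_exponent: int = 1) -> float:
    """Σ_t corrected occupancy · utility / (1 + r)^t.

    ``t`` starts at ``first_cycle_exponent`` (default 1: the first cycle's
    mid-cycle-credited QALYs are discounted one period from the index).
    """
    u = np.asarray(state_utilities, dtype=float)
    if u.shape != (3,):
        raise ValueError("state_utilities must give one utility per state")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("state utilities must lie in [0, 1]")
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.arange(trace.horizon) + first_cycle_exponent
    per_cycle = trace.half_cycle_corrected_occupancy @ u
    return float(np.sum(per_cycle / (1.0 + discount_rate) ** t))


def remaining_qalys(age: int, post_ami: bool, settings: MarkovSettings,
                    utilities: Sequence[float],
                    discount_rate: float) -> float:
    """Discounted remaining QALYs over a lifetime horizon.

    ``post_ami`` starts the cohort in the CVD state.  The horizon runs to
    ``settings.max_age`` or until the alive fraction drops below
    ``settings.alive_tolerance``, whichever comes first.
    """
    schedule = build_schedule(settings, start_age=age)
    trace = run_cohort(schedule,
                       MarkovState.cvd if post_ami else MarkovState.non_cvd)
    alive = trace.alive_fraction()
    below = np.nonzero(alive[1:] < settings.alive_tolerance)[0]
    if below.size:
        h = int(below[0]) + 1
        trace = MarkovTrace(
            start_age=trace.start_age,
            occupancy=trace.occupancy[:h + 1],
            half_cycle_corrected_occupancy=
            trace.half_cycle_corrected_occupancy[:h])
    u = np.asarray(utilities, dtype=float)
    u = np.clip(u * np.array([settings.utility_scale,
                              settings.utility_scale, 1.0]), 0.0, 1.0)
    return discounted_qalys(trace, u, discount_rate,
                            settings.first_cycle_exponent)


@dataclasses.dataclass(frozen=True)
class CalibrationResult:
    settings: MarkovSettings
    mortality_scale: float
    utility_scale: float
    residuals: tuple[float, float]
    achieved: tuple[float, float]


def calibrate_schedules(targets: tuple[float, float],
                        settings: MarkovSettings,
                        base_utilities: Sequence[float],
                        discount_rate: float,
                        tol: float = 0.05,
                        bounds: tuple[float, float] = (1e-3, 1e3),
                        ) -> CalibrationResult:
    """Find (mortality_scale, utility_scale) hitting the QALY anchors.

    ``targets`` are the remaining discounted QALYs at ``settings.start_age``
    for (no event, post-AMI) — the study anchors are (13.3, 11.1).
    Deterministic given the bounds; raises :class:`CalibrationError` with
    bracketing diagnostics when no root lies inside them.
    """
    t_no, t_ami = targets
    if t_no <= 0 or t_ami <= 0:
        raise CalibrationError("targets must be positive")
    lo, hi = bounds

    def evaluate(log_m: float, log_u: float) -> tuple[float, float]:
        s = settings.model_copy(update={
            "mortality_scale": float(np.exp(log_m)),
            "utility_scale": float(np.exp(log_u))})
        return (remaining_qalys(s.start_age, False, s, base_utilities,
                                discount_rate),
                remaining_qalys(s.start_age, True, s, base_utilities,
                                discount_rate))

    def residual(x: np.ndarray) -> list[float]:
        got = evaluate(x[0], x[1])
        return [got[0] - t_no, got[1] - t_ami]

    x0 = np.log([settings.mortality_scale, settings.utility_scale])
    sol = optimize.root(residual, x0, method="hybr",
                        options={"xtol": 1e-12})
    res = residual(sol.x)
    m, u = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    if (not sol.success or max(abs(r) for r in res) > tol
            or not (lo <= m <= hi) or not (lo <= u <= hi)):
        at_lo = evaluate(np.log(lo), 0.0)
        at_hi = evaluate(np.log(hi), 0.0)
        raise CalibrationError(
            f"no calibration within bounds {bounds}: residuals {res}; "
            f"model range at mortality-scale bounds (utility scale 1): "
            f"{at_hi} .. {at_lo}")
    calibrated = settings.model_copy(update={"mortality_scale": m,
                                             "utility_scale": u})
    achieved = evaluate(sol.x[0], sol.x[1])
    return CalibrationResult(settings=calibrated, mortality_scale=m,
                             utility_scale=u,
                             residuals=(res[0], res[1]), achieved=achieved)
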