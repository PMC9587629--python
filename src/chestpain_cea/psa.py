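"""Probabilistic sensitivity analysis of the base-case model.

Each base-case parameter gets a distribution by type — probabilities
beta, costs gamma, length-of-stay means normal truncated at zero —
moment-matched to (mean, SE), with SE defaulting to 20 % of the mean
where no uncertainty is published.  Every draw re-evaluates the full
deterministic cost and QALY pipeline with the sampled values; the result
feeds the cost-effectiveness plane and the acceptability curve (CEAC).

Out-of-range draws are rejected and resampled (with a logged count)
rather than truncated, so the matched moments keep their meaning.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np

from .cea import incremental
from .costing import strategy_total_cost
from .params import ModelParameters, resolve_scenario
from .qaly import strategy_qaly

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "assign_distributions",
    "run_psa",
    "ceac",
    "DEFAULT_LAMBDA_GRID",
]

#: 0 to 150,000 EUR/QALY in 1,000-EUR steps — covers the Norwegian band.
DEFAULT_LAMBDA_GRID = np.arange(0, 150_001, 1000, dtype=float)


@dataclasses.dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: family plus (mean, SE), moment-matched."""

    key: str
    family: str                       # beta | gamma | normal | fixed
    mean: float
    se: float = 0.0
    lower: float = 0.0                # support floor for rejection sampling

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "normal", "fixed"):
            raise ValueError(f"unknown family {self.family!r} for {self.key}")
        if self.family != "fixed" and self.se < 0:
            raise ValueError(f"negative SE for {self.key}")
        if self.family == "beta":
            m, v = self.mean, self.se**2
            if not 0 < m < 1:
                raise ValueError(f"beta mean for {self.key} must lie in (0,1)")
            if v >= m * (1 - m):
                raise ValueError(
                    f"beta variance for {self.key} infeasible: {v} ≥ m(1−m)")
        if self.family == "gamma" and self.mean <= 0 and self.se > 0:
            raise ValueError(f"gamma mean for {self.key} must be positive")

    def sampler(self) -> Callable[[np.random.Generator, int], np.ndarray]:
        m, s = self.mean, self.se
        if self.family == "fixed" or s == 0:
            return lambda rng, size: np.full(size, m)
        if self.family == "beta":
            k = m * (1 - m) / s**2 - 1.0
            a, b = m * k, (1 - m) * k
            return lambda rng, size: rng.beta(a, b, size)
        if self.family == "gamma":
            shape = (m / s) ** 2
            scale = s**2 / m
            return lambda rng, size: rng.gamma(shape, scale, size)
        return lambda rng, size: rng.normal(m, s, size)   # truncated by rejection


def assign_distributions(params: ModelParameters,
                         relative_se: float = 0.2,
                         overrides: Mapping[str, ParameterDistribution]
                         | None = None) -> dict[str, ParameterDistribution]:
    """Distribution set for the base-case parameters.

    Keys are dotted parameter paths into :class:`ModelParameters`.
    ``relative_se`` sets SE = 20 % of the mean wherever no published
    uncertainty exists; individual entries can be overridden, e.g. to pin
    a parameter with ``family="fixed"``.
    """
    c, t, u = params.costs, params.time, params.utility
    spec: dict[str, tuple[str, float]] = {
        "costs.ems_cost_per_transport": ("gamma", c.ems_cost_per_transport),
        "costs.p_ambulance_to_primary": ("beta", c.p_ambulance_to_primary),
        "costs.p_ambulance_to_hospital_base":
            ("beta", c.p_ambulance_to_hospital_base),
        "costs.consultation_cost": ("gamma", c.consultation_cost),
        "costs.algorithm_lab_cost": ("gamma", c.algorithm_lab_cost),
        "costs.personnel_cost_wage": ("gamma", c.personnel_cost_wage),
        "costs.outpatient_referral_cost": ("gamma", c.outpatient_referral_cost),
        "costs.drg_total": ("gamma", c.drg_total),
        "time.los_primary_base_mean_h": ("normal", t.los_primary_base_mean_h),
        "time.los_hospital_mean_h": ("normal", t.los_hospital_mean_h),
        "utility.waiting_utility_decrement":
            ("beta", u.waiting_utility_decrement),
    }
    dists = {key: ParameterDistribution(key=key, family=family, mean=mean,
                                        se=relative_se * mean)
             for key, (family, mean) in spec.items()}
    if overrides:
        for key, dist in overrides.items():
            dists[key] = dist
    return dists


@dataclasses.dataclass(frozen=True)
class PSAResult:
    n_draws: int
    seed: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n_rejected: int

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_delta_qaly(self) -> float:
        return float(self.delta_qaly.mean())


def _apply_overrides(params: ModelParameters,
                     values: Mapping[str, float]) -> ModelParameters:
    by_section: dict[str, dict[str, float]] = {}
    for key, value in values.items():
        section, field = key.split(".", 1)
        by_section.setdefault(section, {})[field] = float(value)
    updates = {section: getattr(params, section).model_copy(update=fields)
               for section, fields in by_section.items()}
    return params.model_copy(update=updates)


def _evaluate_base_case(params: ModelParameters) -> tuple[float, float]:
    """Deterministic base-case (ΔCost, ΔQALY) with report rounding."""
    from .pipeline import strategy_outcome   # local import: avoid cycle
    scenario = resolve_scenario(params, "base_case")
    primary = strategy_outcome(scenario, "primary_care_algorithm", params)
    hospital = strategy_outcome(scenario, "hospital_standard", params)
    return incremental(primary, hospital)


def run_psa(distributions: Mapping[str, ParameterDistribution],
            params: ModelParameters, n_draws: int, seed: int,
            max_rejections: int = 100) -> PSAResult:
    """Monte-Carlo propagation through the deterministic base-case model.

    Deterministic given ``seed``.  Draws that land outside a parameter's
    support (negative cost or LOS, probability outside [0, 1]) are
    rejected and redrawn; the count is recorded on the result.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    rng = np.random.default_rng(seed)
    keys = list(distributions)
    samples = np.empty((n_draws, len(keys)))
    n_rejected = 0
    for j, key in enumerate(keys):
        dist = distributions[key]
        draw = dist.sampler()(rng, n_draws)
        ok = _in_support(draw, dist)
        tries = 0
        while not ok.all():
            tries += 1
            if tries > max_rejections:
                raise RuntimeError(f"resampling for {key} did not terminate")
            bad = ~ok
            n_rejected += int(bad.sum())
            draw[bad] = dist.sampler()(rng, int(bad.sum()))
            ok = _in_support(draw, dist)
        samples[:, j] = draw
    delta_cost = np.empty(n_draws)
    delta_qaly = np.empty(n_draws)
    for i in range(n_draws):
        values = dict(zip(keys, samples[i]))
        dc, dq = _evaluate_base_case(_apply_overrides(params, values))
        delta_cost[i] = dc
        delta_qaly[i] = dq
    return PSAResult(n_draws=n_draws, seed=seed, delta_cost=delta_cost,
                     delta_qaly=delta_qaly, n_rejected=n_rejected)


def _in_support(draw: np.ndarray, dist: ParameterDistribution) -> np.ndarray:
    ok = draw >= dist.lower
    if dist.family == "beta" or dist.key.split(".")[-1].startswith("p_"):
        ok &= draw <= 1.0
    if dist.family in ("normal", "gamma"):
        ok &= draw >= 0.0
    return ok


def ceac(result: PSAResult,
         lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
         ) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve.

    At each willingness-to-pay λ, the probability of cost-effectiveness is
    the fraction of draws with positive net monetary benefit
    λ·ΔQALY − ΔCost > 0.
    """
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("lambda grid must be non-negative")
    if result.n_draws == 0:
        raise ValueError("no PSA draws")
    nmb = grid[:, None] * result.delta_qaly[None, :] - result.delta_cost[None, :]
    prob = (nmb > 0).mean(axis=1)
    return [(float(l), float(p)) for l, p in zip(grid, prob)]
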