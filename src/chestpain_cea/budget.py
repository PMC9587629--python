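"""National budget impact of moving low-risk rule-out into primary care.

Scales the per-patient saving to the Norwegian system: of the annual
hospital discharges with non-specific chest pain (ICD-10 R07) referred
from an out-of-hours (OOH) assessment, the fraction whose OOH clinic lies
within an acceptable distance of an hs-cTn laboratory could be assessed
with the 0/1-h algorithm instead; 13.2 % of those would still be
admitted and 86.8 % discharged home, each discharge saving the
per-patient cost difference.

Coverage by distance is a step-function lookup into a table of
(distance, population covered, national fraction); no geographic
computation happens here — the fractions are inputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from ._rounding import round_half_up

__all__ = [
    "CoverageRow",
    "CoverageTable",
    "NationalInputs",
    "eligible_patients",
    "annual_savings",
    "coverage_at",
]

NATIONAL_POPULATION_2020 = 5_367_580


@dataclasses.dataclass(frozen=True)
class CoverageRow:
    distance_km: float
    population: float
    fraction: float


@dataclasses.dataclass(frozen=True)
class CoverageTable:
    """Population covered by OOH clinics within a distance of an hs-cTn lab.

    Ships with the two published anchor tiers — clinics on hospital
    grounds (1.7 M people, 31.4 %) and a 20-km limit (4.0 M, 74.7 %) —
    and accepts further tiers from configuration or CSV.
    """

    rows: tuple[CoverageRow, ...]
    national_population: int = NATIONAL_POPULATION_2020

    def __post_init__(self) -> None:
        rows = tuple(sorted(self.rows, key=lambda r: r.distance_km))
        last = -1.0
        for r in rows:
            if not 0.0 <= r.fraction <= 1.0:
                raise ValueError(f"coverage fraction outside [0,1] at {r.distance_km} km")
            if r.fraction < last:
                raise ValueError("coverage fraction must be non-decreasing in distance")
            last = r.fraction
        object.__setattr__(self, "rows", rows)

    @classmethod
    def default(cls) -> "CoverageTable":
        return cls(rows=(CoverageRow(0.0, 1.7e6, 0.314),
                         CoverageRow(20.0, 4.0e6, 0.747)))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoverageTable":
        rows = tuple(CoverageRow(float(r.distance_km), float(r.population),
                                 float(r.fraction))
                     for r in df.itertuples())
        return cls(rows=rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.rows])


def coverage_at(table: CoverageTable,
                distance_km: float) -> CoverageRow:
    """Step-function lookup: the largest tier at or below ``distance_km``.

    Distances below the smallest tier return the on-site tier; distances
    beyond the table return its largest tier.
    """
    if distance_km < 0:
        raise ValueError("distance must be non-negative")
    chosen = table.rows[0]
    for row in table.rows:
        if row.distance_km <= distance_km:
            chosen = row
    return chosen


@dataclasses.dataclass(frozen=True)
class NationalInputs:
    """Annual national counts and the split under the 0/1-h algorithm."""

    ooh_referred_admissions: int = 7613   # R07 discharges referred from OOH
    total_r07_discharges: int = 16_320
    discharge_fraction: float = 0.868
    admit_fraction: float = 0.132
    saving_per_patient_low: float = 1672.0
    saving_per_patient_high: float = 1794.0

    def __post_init__(self) -> None:
        if abs(self.discharge_fraction + self.admit_fraction - 1.0) > 1e-9:
            raise ValueError("discharge and admit fractions must sum to 1")


@dataclasses.dataclass(frozen=True)
class EligibleCounts:
    assessed: int
    hospitalised: int
    discharged: int


def eligible_patients(inputs: NationalInputs,
                      coverage_fraction: float) -> EligibleCounts:
    """Patients reachable by the algorithm at a given coverage fraction.

    Rounding policy: round the assessed count first, round the admitted
    split, and take discharged as the remainder — so the three counts
    always reconcile (published chain: 7613 → 5687 → 751 + 4936).
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage fraction must lie in [0, 1]")
    assessed = int(round_half_up(inputs.ooh_referred_admissions
                                 * coverage_fraction))
    hospitalised = int(round_half_up(assessed * inputs.admit_fraction))
    return EligibleCounts(assessed=assessed, hospitalised=hospitalised,
                          discharged=assessed - hospitalised)


@dataclasses.dataclass(frozen=True)
class AnnualSavings:
    total_eur: float
    millions_eur: float


def annual_savings(discharged: int,
                   saving_per_patient: float) -> AnnualSavings:
    """Annual system saving: discharged count × per-patient saving."""
    if discharged < 0 or saving_per_patient < 0:
        raise ValueError("inputs must be non-negative")
    total = discharged * saving_per_patient
    return AnnualSavings(total_eur=total,
                         millions_eur=round_half_up(total / 1e6, 1))


def budget_report(inputs: NationalInputs, table: CoverageTable,
                  distances_km: Sequence[float] = (0.0, 20.0)) -> pd.DataFrame:
    """Savings per coverage tier at both per-patient saving bounds."""
    rows = []
    for d in distances_km:
        cov = coverage_at(table, d)
        counts = eligible_patients(inputs, cov.fraction)
        for label, saving in (("conservative", inputs.saving_per_patient_low),
                              ("base_case", inputs.saving_per_patient_high)):
            s = annual_savings(counts.discharged, saving)
            rows.append({"distance_km": d, "coverage_fraction": cov.fraction,
                         "population": cov.population,
                         "assessed": counts.assessed,
                         "hospitalised": counts.hospitalised,
                         "discharged": counts.discharged,
                         "scenario": label, "saving_per_patient": saving,
                         "annual_saving_eur": s.total_eur,
                         "annual_saving_millions": s.millions_eur})
    return pd.DataFrame(rows)
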