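"""Seeded synthetic patient-level cohorts.

Stands in for the two observed low-risk chest-pain cohorts the analysis
rests on: an emergency-primary-care cohort triaged by the 0/1-h hs-cTnT
algorithm (n = 1711; rule-out / observation / rule-in counts
1311 / 334 / 66; 13.2 % admitted; 30-day AMI-or-death rate 0.3 % among
those sent home) and a hospital cohort of low-risk admissions (n = 567;
length of stay 22.3 h with SD ≈ mean, i.e. strongly right-skewed;
31.9 % receiving additional advanced procedures; mean DRG cost EUR 1483).

Only marginals are emulated: length of stay is lognormal by moment
matching, hospital costs are gamma with a configurable coefficient of
variation, and triage / admission / procedure / event indicators are
independent draws — the source data publish no joint structure.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CohortSpec",
    "CohortSummary",
    "primary_care_spec",
    "hospital_spec",
    "generate_cohort",
    "summarize_cohort",
    "write_cohort",
    "read_cohort",
]

TRIAGE_CLASSES = ("rule_out", "observation", "rule_in")

#: Observed triage split 1311 / 334 / 66 of 1711 (76.6 / 19.5 / 3.9 %);
#: exact count ratios so the fractions sum to 1.
DEFAULT_TRIAGE_FRACTIONS = (1311 / 1711, 334 / 1711, 66 / 1711)
EVENT_TYPES = ("none", "ami", "death")

RECORD_COLUMNS = ["patient_id", "setting", "triage", "admitted", "los_hours",
                  "n_advanced_procedures", "cost_eur", "event_30d",
                  "ambulance"]


class CohortSpec(BaseModel):
    """Marginal targets for one generated cohort."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    setting: Literal["primary_care", "hospital"]
    n: int = Field(ge=0)
    seed: int
    triage_fractions: tuple[float, float, float] = DEFAULT_TRIAGE_FRACTIONS
    p_admit: float = Field(0.132, ge=0, le=1)
    los_mean_h: float = Field(gt=0)
    los_sd_h: float = Field(ge=0)
    p_procedures: float = Field(0.319, ge=0, le=1)
    event_rate_30d: float = Field(ge=0, le=1)
    p_death_given_event: float = Field(0.2, ge=0, le=1)
    mean_cost_eur: float | None = None       # hospital records only
    cost_cv: float = Field(0.5, gt=0)        # gamma coefficient of variation
    p_ambulance: float | None = None         # optional per-record indicator

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if abs(sum(self.triage_fractions) - 1.0) > 1e-9:
            raise ValueError("triage fractions must sum to 1")
        if any(f < 0 for f in self.triage_fractions):
            raise ValueError("triage fractions must be non-negative")
        if self.setting == "hospital" and self.mean_cost_eur is None:
            raise ValueError("hospital cohorts need mean_cost_eur")
        if self.p_ambulance is not None and not 0 <= self.p_ambulance <= 1:
            raise ValueError("p_ambulance must lie in [0, 1]")
        return self


def primary_care_spec(n: int = 1711, seed: int = 0, **overrides) -> CohortSpec:
    """Defaults matching the observed primary-care (0/1-h algorithm) cohort."""
    kw = dict(setting="primary_care", n=n, seed=seed,
              los_mean_h=3.4, los_sd_h=0.740,
              event_rate_30d=5 / 1485)
    kw.update(overrides)
    return CohortSpec(**kw)


def hospital_spec(n: int = 567, seed: int = 0, **overrides) -> CohortSpec:
    """Defaults matching the observed low-risk hospital cohort."""
    kw = dict(setting="hospital", n=n, seed=seed,
              los_mean_h=22.3, los_sd_h=22.010,
              event_rate_30d=2 / 862, mean_cost_eur=1483.0,
              p_admit=1.0)
    kw.update(overrides)
    return CohortSpec(**kw)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    cv2 = (sd / mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic-given-seed patient-level cohort.

    Length of stay: lognormal moment-matched to (mean, SD); SD = 0
    degenerates to a point mass.  Hospital costs: gamma with the configured
    mean and coefficient of variation.  Triage, admission, procedures, events
    and (optionally) ambulance use are independent categorical draws.
    """
    if spec.n < 0:
        raise ValueError("cohort size must be non-negative")
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["patient_id"] = [f"{spec.setting[:4]}-{spec.seed}-{i:06d}"
                        for i in range(n)]
    df["setting"] = spec.setting
    if spec.setting == "primary_care":
        df["triage"] = rng.choice(TRIAGE_CLASSES, size=n,
                                  p=spec.triage_fractions)
        df["admitted"] = rng.random(n) < spec.p_admit
    else:
        df["triage"] = "not_applicable"
        df["admitted"] = rng.random(n) < spec.p_admit
    if spec.los_sd_h == 0:
        df["los_hours"] = float(spec.los_mean_h)
    else:
        mu, sigma = _lognormal_params(spec.los_mean_h, spec.los_sd_h)
        df["los_hours"] = rng.lognormal(mu, sigma, size=n)
    df["n_advanced_procedures"] = (rng.random(n) < spec.p_procedures).astype(int)
    if spec.setting == "hospital":
        shape = 1.0 / spec.cost_cv**2
        scale = spec.mean_cost_eur / shape
        df["cost_eur"] = rng.gamma(shape, scale, size=n)
    else:
        df["cost_eur"] = np.nan
    event = rng.random(n) < spec.event_rate_30d
    death = rng.random(n) < spec.p_death_given_event
    df["event_30d"] = np.where(event, np.where(death, "death", "ami"), "none")
    if spec.p_ambulance is not None:
        df["ambulance"] = rng.random(n) < spec.p_ambulance
    else:
        df["ambulance"] = False
    return df[RECORD_COLUMNS]


@dataclasses.dataclass(frozen=True)
class CohortSummary:
    """Exact empirical marginals of a cohort; ``n == 0`` is the empty sentinel."""

    n: int
    p_admit: float = float("nan")
    triage_fractions: tuple[float, float, float] = (float("nan"),) * 3
    los_mean_h: float = float("nan")
    los_sd_h: float = float("nan")          # population SD (ddof=0)
    los_sumsq: float = float("nan")         # retained so summaries merge exactly
    p_procedures: float = float("nan")
    event_rate_30d: float = float("nan")
    mean_cost_eur: float = float("nan")

    @property
    def empty(self) -> bool:
        return self.n == 0

    def combine(self, other: "CohortSummary") -> "CohortSummary":
        """Weighted merge: equals the summary of the concatenated records."""
        if self.empty:
            return other
        if other.empty:
            return self
        n = self.n + other.n
        w1, w2 = self.n / n, other.n / n

        def wmean(a: float, b: float) -> float:
            if np.isnan(a) and np.isnan(b):
                return float("nan")
            return w1 * (0.0 if np.isnan(a) else a) + w2 * (0.0 if np.isnan(b) else b)

        tri = tuple(w1 * a + w2 * b for a, b in
                    zip(self.triage_fractions, other.triage_fractions))
        mean = w1 * self.los_mean_h + w2 * other.los_mean_h
        sumsq = self.los_sumsq + other.los_sumsq
        var = sumsq / n - mean**2
        return CohortSummary(
            n=n, p_admit=w1 * self.p_admit + w2 * other.p_admit,
            triage_fractions=tri, los_mean_h=mean,
            los_sd_h=float(np.sqrt(max(var, 0.0))), los_sumsq=sumsq,
            p_procedures=w1 * self.p_procedures + w2 * other.p_procedures,
            event_rate_30d=w1 * self.event_rate_30d + w2 * other.event_rate_30d,
            mean_cost_eur=wmean(self.mean_cost_eur, other.mean_cost_eur)
            if not (np.isnan(self.mean_cost_eur) and np.isnan(other.mean_cost_eur))
            else float("nan"),
        )


def summarize_cohort(records: pd.DataFrame) -> CohortSummary:
    """Empirical marginals (fractions, means, population SDs) of a cohort."""
    if records is None or len(records) == 0:
        return CohortSummary(n=0)
    n = len(records)
    tri = tuple(float((records["triage"] == c).mean()) for c in TRIAGE_CLASSES)
    los = records["los_hours"].to_numpy(dtype=float)
    cost = records["cost_eur"].to_numpy(dtype=float)
    return CohortSummary(
        n=n,
        p_admit=float(records["admitted"].mean()),
        triage_fractions=tri,
        los_mean_h=float(los.mean()),
        los_sd_h=float(los.std(ddof=0)),
        los_sumsq=float((los**2).sum()),
        p_procedures=float((records["n_advanced_procedures"] > 0).mean()),
        event_rate_30d=float((records["event_30d"] != "none").mean()),
        mean_cost_eur=float(np.nanmean(cost)) if np.isfinite(cost).any()
        else float("nan"),
    )


def write_cohort(records: pd.DataFrame, path: str | pathlib.Path,
                 spec: CohortSpec | None = None) -> None:
    """CSV writer; the generating spec (seed included) goes in a sidecar
    ``<path>.meta.json`` so a cohort on disk is reproducible."""
    path = pathlib.Path(path)
    records.to_csv(path, index=False)
    if spec is not None:
        meta = {"spec": spec.model_dump(), "n_rows": int(len(records))}
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(meta, indent=2))


def read_cohort(path: str | pathlib.Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    return df
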