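"""Expected confusion counts for a triage test at a given prevalence.

Used for the worked example on rule-in performance: among 1000 patients
with a 3.6 % AMI prevalence, a test with sensitivity 73.8 % and
specificity 98.7 % yields 36 expected AMIs and about 13 false positives.
Unrounded expectations are always retained; nearest-integer rounding
(ties away from zero) is applied only for display.
"""

from __future__ import annotations

import dataclasses

from ._rounding import round_half_up

__all__ = ["TestPerformance", "ConfusionCounts", "expected_confusion"]


@dataclasses.dataclass(frozen=True)
class TestPerformance:
    __test__ = False   # not a test case, despite the name

    sensitivity: float = 0.738
    specificity: float = 0.987
    prevalence: float = 0.036

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    n: float
    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def diseased(self) -> float:
        return self.tp + self.fn

    @property
    def ppv(self) -> float:
        """Positive predictive value, on unrounded expectations."""
        pos = self.tp + self.fp
        return self.tp / pos if pos else float("nan")

    @property
    def npv(self) -> float:
        neg = self.tn + self.fn
        return self.tn / neg if neg else float("nan")

    def rounded(self) -> dict[str, int]:
        return {k: int(round_half_up(getattr(self, k)))
                for k in ("tp", "fp", "tn", "fn")}


def expected_confusion(n: float,
                       performance: TestPerformance) -> ConfusionCounts:
    """Expected TP/FP/TN/FN among ``n`` patients."""
    if n < 0:
        raise ValueError("n must be non-negative")
    p = performance
    diseased = n * p.prevalence
    healthy = n - diseased
    return ConfusionCounts(
        n=n,
        tp=diseased * p.sensitivity,
        fn=diseased * (1.0 - p.sensitivity),
        tn=healthy * p.specificity,
        fp=healthy * (1.0 - p.specificity),
    )
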