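#!/usr/bin/env python
"""Generate the two synthetic study cohorts and check their marginals.

Emulates the primary-care cohort assessed with the 0/1-h hs-cTnT
algorithm (n = 1711) and the low-risk hospital cohort (n = 567), writes
them as CSV with sidecar metadata, and prints the empirical marginals
next to their calibration targets.  Everything downstream is analytic;
these records exist for the bottom-up costing cross-check and as a
patient-level stand-in for the study data.
"""

import pathlib

import pandas as pd

from chestpain_cea.cohort import (generate_cohort, hospital_spec,
                                  primary_care_spec, summarize_cohort,
                                  write_cohort)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "cohorts"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec, targets in [
        (primary_care_spec(seed=SEED),
         {"p_admit": 0.132, "los_mean_h": 3.4, "event_rate_30d": 5 / 1485}),
        (hospital_spec(seed=SEED + 1, p_ambulance=0.90),
         {"los_mean_h": 22.3, "mean_cost_eur": 1483.0}),
    ]:
        records = generate_cohort(spec)
        write_cohort(records, OUT / f"{spec.setting}.csv", spec)
        s = summarize_cohort(records)
        for field, target in targets.items():
            rows.append({"cohort": spec.setting, "marginal": field,
                         "target": target, "observed": getattr(s, field),
                         "n": s.n})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "marginal_check.csv", index=False)
    print(f"Wrote cohorts and marginal check to {OUT}")
    print(table.to_string(index=False))
    print("\nAt the study sample sizes the empirical marginals scatter "
          "around their targets; the test suite checks them at n = 10^5 "
          "within 3 Monte-Carlo SEs.")


if __name__ == "__main__":
    main()
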