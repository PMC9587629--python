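#!/usr/bin/env python
"""National budget impact by distance coverage to an hs-cTn laboratory.

Of the 7613 annual Norwegian hospital admissions with non-specific chest
pain referred from out-of-hours care, the share whose clinic lies within
a given distance of an hs-cTn lab could be triaged with the 0/1-h
algorithm.  At the 20-km tier (74.7 % of the population) 5687 patients
would be assessed, 751 still admitted and 4936 discharged home, saving
EUR 8.3 million per year at the conservative per-patient saving (EUR
1672) and EUR 8.9 million at the base-case saving (EUR 1794, direct
product).
"""

import pathlib

from chestpain_cea.budget import (CoverageTable, NationalInputs,
                                  budget_report)

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = budget_report(NationalInputs(), CoverageTable.default())
    report.to_csv(OUT / "budget_impact.csv", index=False)
    print(report.to_string(index=False))
    print("\nOn-site tier covers 31.4 % of the population; the 20-km tier "
          "74.7 %.  Savings scale linearly in both the discharged count "
          "and the per-patient saving.")


if __name__ == "__main__":
    main()
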