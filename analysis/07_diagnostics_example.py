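#!/usr/bin/env python
"""Worked example: rule-in performance at low AMI prevalence.

Among 1000 patients with a 3.6 % AMI prevalence, a rule-in arm with
sensitivity 73.8 % and specificity 98.7 % is expected to contain 36
patients with an AMI and about 13 false positives — the price of
implementing a highly specific test in a low-prevalence setting.
"""

import json
import pathlib

from chestpain_cea.diagnostics import TestPerformance, expected_confusion

OUT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    perf = TestPerformance()
    c = expected_confusion(1000, perf)
    payload = {"n": c.n, "prevalence": perf.prevalence,
               "sensitivity": perf.sensitivity,
               "specificity": perf.specificity,
               "expected": {"tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn},
               "rounded": c.rounded(), "ppv": c.ppv, "npv": c.npv}
    (OUT / "diagnostics_example.json").write_text(
        json.dumps(payload, indent=2))
    print(f"Expected AMIs among 1000: {c.diseased:.1f} (≈ 36)")
    print(f"Expected false positives in the rule-in group: {c.fp:.2f} (≈ 13)")
    print(f"PPV {c.ppv:.3f}, NPV {c.npv:.4f}")


if __name__ == "__main__":
    main()
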