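# chestpain-cea

Cost-effectiveness analysis of assessing **low-risk chest-pain patients
with the ESC 0/1-h high-sensitivity cardiac troponin T (hs-cTnT)
algorithm in emergency primary care**, compared with routine hospital
admission, in the Norwegian out-of-hours (OOH) system.

The package is for health economists and health-services researchers who
want to reproduce, stress or extend the analysis: a deterministic
decision-tree cost model, a QALY model for waiting time and excess
30-day events, a three-state Markov model supplying lifetime QALY
anchors, incremental cost-effectiveness analysis with quadrant
semantics, probabilistic sensitivity analysis (PSA) with a
cost-effectiveness acceptability curve (CEAC), a national budget-impact
module, a diagnostic worked example, and a seeded synthetic-cohort
generator standing in for the patient-level study data.

## The model

Two strategies for a low-risk patient presenting with chest pain:

* **Primary care + 0/1-h algorithm** — cost
  `C_p = p_EMS·c_EMS + c_consult + (c_lab + c_personnel + c_outpatient)`
* **Hospital standard** — cost
  `C_h = p_EMS·c_EMS + c_consult + p_amb·c_EMS + c_DRG`

with `c_DRG` the mean diagnosis-related-group cost of a low-risk
admission (EUR 840,664 / 567 = 1483).  Health effects are QALY losses

```
Q_LOS   = −(LOS_hours / 8766) · d          d = annualised waiting decrement
Q_event = −r_30d · ΔQALY_event             ΔQALY_event = lifetime discounted
                                           QALYs (no event) − (post-AMI)
```

where `ΔQALY_event` comes from a three-state (non-CVD / CVD / dead)
Markov cohort model with one-year cycles, half-cycle correction, 4 %
discounting, Gompertz background mortality and a CVD mortality hazard
ratio of 1.6, calibrated to the anchors 13.3 / 11.1 remaining QALYs at
age 56.  Incremental results are classified on the cost-effectiveness
plane (`dominant`, `dominated`, NE/SW trade-offs); net monetary benefit
is `NMB(λ) = λ·ΔQALY − ΔCost`; the Norwegian willingness-to-pay band is
EUR 25,600–76,900 per QALY.

## Worked example

```python
from chestpain_cea import load_parameters, resolve_scenario, strategy_outcome
from chestpain_cea.cea import incremental, icer

params = load_parameters()                      # study defaults
base = resolve_scenario(params, "base_case")
prim = strategy_outcome(base, "primary_care_algorithm", params)
hosp = strategy_outcome(base, "hospital_standard", params)
print(prim.cost.total, hosp.cost.total)         # 520 2314
dc, dq = incremental(prim, hosp)
print(dc, round(dq, 5))                         # -1794.0 0.0005
print(icer(dc, dq).quadrant.value)              # dominant
```

Assessing a low-risk patient in primary care costs EUR 520 against
EUR 2314 in hospital: the strategy saves EUR 1794 per patient, shortens
the stay by 18.9 h and gains 0.0005 QALYs — cheaper *and* more
effective, hence dominant.  Under the deliberately conservative scenario
(tariff-costed personnel, excess event rate, lower ambulance
probability, longer primary-care stay) it saves EUR 1672 while losing
QALYs; at the quoted precision (−1672 / −0.0019) the savings amount to
EUR 880,000 per QALY lost, far above the willingness-to-accept band, so
the strategy remains cost-effective.

The numbered drivers under `analysis/` run each stage end to end and
write their tables under `results/`:

```bash
python analysis/02_cost_qaly_table.py      # summary cost/LOS/QALY table
python analysis/05_psa.py                  # 10,000-draw PSA + CEAC
```

There is also a CLI: `chestpain-cea --help` (subcommands `cost`, `qaly`,
`markov`, `cea`, `psa`, `budget`, `diagnostics`, `cohort`, `report`,
`all`).  A fully explicit parameter file ships in `config/default.yaml`;
pass `--config` to override any value.

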