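# Methods

## Setting and question

In the Norwegian system, primary care gatekeeps hospital admission.
Patients with chest pain judged low risk for non-ST-elevation acute
coronary syndrome are, in most regions, admitted to hospital for serial
troponin measurement; an emergency primary-care clinic with access to an
hs-cTnT assay can instead triage them with the ESC 0/1-h algorithm and
send most home the same evening.  The analysis compares the expected
cost and health consequences per low-risk patient of the two pathways,
then scales the difference to the national level.

## Decision-tree costing

Each arm is a sum of expected cost components, `E[c] = p · unit_cost`,
in 2020 EUR (NOK converted at 10.73).  Micro-costing follows the
Norwegian guideline conventions: wages are multiplied by 1.3 for payroll
taxes and social charges; HELFO reimbursements for primary-care services
are doubled to cover the remaining financing sources (`gross_up`).  Both
arms share the initial EMS-to-clinic transport (EUR 559 at probability
0.29) and the general consultation (EUR 166); these are implemented as
literally shared components, so they cancel structurally in the
incremental cost.  The primary-care arm adds the algorithm add-on
(laboratory EUR 41, personnel EUR 99 wage-costed or EUR 137
tariff-costed, outpatient referral EUR 52); the hospital arm adds the
ambulance transfer (probability 0.90 base case, 0.75 conservative) and
the mean DRG cost EUR 1483.

Components are rounded to whole EUR *before* totalling: the published
totals (520 / 2314 / 558 / 2230) are sums of the published rounded
cells, and this package reproduces that convention while retaining the
unrounded values on every component.  Half-way cases round away from
zero.

A bottom-up path (`cost_from_records`) prices patient-level records and
is used as a Monte-Carlo cross-check of the analytic tree on large
synthetic cohorts (agreement within 3 Monte-Carlo SEs).

## QALY model

Waiting under assessment costs `(LOS_hours / hours_per_year) × d` QALYs
with `d = 0.232` per year.  `hours_per_year` defaults to 8766
(365.25 × 24); 8760 reproduces the same cells at the printed rounding.
The decrement is not a printed constant: it is the value implied jointly
by the printed pairs (22.3 h → 0.00059) and (3.4 h → 0.00009), exposed
in configuration.

Excess 30-day AMI/death events cost `r × δ` QALYs, with rates 5/1485
(primary, non-admitted) and 2/862 (hospital) and `δ = 2.222` the
lifetime discounted QALY loss per event.  `δ` is likewise a calibrated
value: the printed anchors are 13.3 remaining QALYs without an event and
11.1 after an AMI, and the printed cells imply δ between 2.2197 and
2.2245 — no single value reproduces both cells at five decimals, so the
conservative event cells render as −0.00748 / −0.00516 against the
published −0.00749 / −0.00515 (within 1e-5, which is the tolerance used
throughout).  The base case sets the event loss to zero in both arms
(observed rates are below the accepted ≤ 1 % miss rate).  The same δ is
applied to AMI and death jointly; the source evidence does not separate
them.

QALY report cells follow the same convention as costs: components
rounded (five decimals) before summation; unrounded totals are carried
alongside and used for all further computation.

## Long-term Markov model

Three states — non-CVD, CVD, dead (absorbing) — with one-year cycles
from age 56, half-cycle correction (each cycle credited with the mean of
its start- and end-occupancy), and 4 % annual discounting with the first
corrected cycle discounted one period (`first_cycle_exponent = 1`,
configurable; the convention is not dictated by the source).  Background
mortality is Gompertz, `q(a) = 1 − exp(−b·e^{θa})` with defaults
`b = 2·10⁻⁵`, `θ = 0.095` (≈ 0.4 % annual mortality at 56, a plausible
general-population level); annual CVD incidence defaults to 1 %.  Living
with CVD multiplies the mortality *hazard* by 1.6, applied on the
survival scale as `1 − (1 − q)^{1.6}` so probabilities never leave
[0, 1] even for q near 1 (naive multiplication would).

Because the life-table and incidence inputs behind the published anchors
are not part of the printed evidence, the model is calibrated: a
two-dimensional root-find (scipy `hybr`, parameters log-transformed to
stay positive) adjusts a mortality scale on `b` and a global utility
scale on the state utilities (defaults 0.85 non-CVD, 0.74 CVD) until
remaining discounted QALYs at 56 hit 13.3 (start non-CVD) and 11.1
(start CVD) within 0.05.  The calibrated solution is ≈ (0.496, 0.889).
These anchors are calibration *targets*, not independent predictions of
the model; the engine itself is verified against an explicit per-year
scalar loop on randomised instances, occupancy-conservation to 1e-12,
discount-rate monotonicity, half-cycle bounds (corrected QALYs strictly
between the start- and end-of-cycle accumulation variants) and hazard-
ratio-1 label symmetry.  The lifetime horizon ends at age 110 or when
the alive fraction drops below 1e-6.  No costs accrue inside the Markov
model; long-term differences enter through QALYs only.

## Incremental analysis

Differences are primary-care minus hospital; QALY differences are
computed on losses, so positive ΔQALY favours primary care.  Dominant /
dominated quadrants report no ratio.  In the southwest quadrant (cheaper
but less effective) the strategy is acceptable when the savings per QALY
lost are at least the threshold (ICER ≥ λ) — the rule under which EUR
880,000 saved per QALY lost is clearly acceptable against a band of
25,600–76,900.  Boundary ICERs equal to the threshold count as
cost-effective; ΔQALY = 0 degenerates to a cost-only comparison.

The published conservative ratio EUR 880,000/QALY follows from the pair
at quoted precision (−1672 / −0.0019).  This package's unrounded chain
gives ΔQALY −0.00184 and a ratio ≈ EUR 908,000/QALY; the gap traces
entirely to the δ ambiguity above.  Both values are reported, labelled;
the decision (cost-effective across the whole band) is identical under
either.

## Probabilistic sensitivity analysis

Base-case parameters receive distributions by type — probabilities beta,
costs gamma, LOS means normal truncated at zero — moment-matched to
(mean, SE) with SE defaulting to 20 % of the mean; families and SEs are
package conventions (the source defers its specifics to supplementary
material) and every entry is overridable, including pinning with
`fixed`.  Out-of-range draws are rejected and resampled with a logged
count, rather than truncated, so matched moments keep their meaning.
Each draw re-evaluates the full deterministic costing + QALY pipeline;
all-fixed distributions therefore collapse the PSA to the deterministic
result exactly.  The CEAC reports, per willingness-to-pay λ on a default
grid of 0–150,000 EUR/QALY in 1,000-EUR steps, the fraction of draws
with positive net monetary benefit.  With a dominant base case the curve
is ≈ 1 across the Norwegian band.  Default run: 10,000 draws, seeded
(`numpy.random.default_rng`); identical seeds give identical results.

## Budget impact

Of 7613 annual R07 (non-specific chest pain) hospital discharges
referred from OOH assessment, the share within reach of an hs-cTn
laboratory is a step-function lookup in a coverage table shipped with
the two published anchor tiers (on hospital grounds: 1.7 M people,
31.4 % of the 2020 population of 5,367,580; within 20 km: 4.0 M,
74.7 %); further tiers are configurable.  Rounding policy: round the
assessed count, round the admitted split, take discharged as the
remainder, so the chain 7613 → 5687 → 751 + 4936 always reconciles.
Annual saving is the direct product of discharged count and per-patient
saving: 4936 × 1672 = EUR 8.3 M (conservative).  With the base-case
saving the direct product is 4936 × 1794 ≈ EUR 8.9 M; the source quotes
8.6 M for this bound, which is not reproducible by direct
multiplication and whose intermediate rounding is unstated — the package
reports the direct product and does not attempt to guess the published
path.

## Synthetic cohorts

The generator emulates only the *marginals* the analysis consumes:
triage split by exact observed counts (1311/334/66 of 1711 — the
published percentage for the observation group, 20.5, is inconsistent
with the counts and with the published 80.5 % conclusive-triage figure,
so the counts govern), admission Bernoulli(0.132), length of stay
lognormal moment-matched to (mean, SD) — hospital LOS has SD ≈ mean,
i.e. strong right skew, which motivates the family — hospital cost gamma
with mean EUR 1483 and a default coefficient of variation 0.5 (not
source-anchored; configurable), procedures Bernoulli(0.319), 30-day
events Bernoulli at the observed rates with an AMI:death split of 4:1
matching the observed event tally.  All draws are independent: the
source publishes no joint structure, so correlations between, e.g., LOS
and events in real data are *not* emulated, and tests passing on these
cohorts validate the pipeline's arithmetic, not clinical realism.  An
optional per-record ambulance indicator supports the bottom-up costing
cross-check.  Cohorts are deterministic given a seed and round-trip
through CSV with a sidecar metadata file echoing the generating spec.

## Numerical conventions and problem sizes

Monetary and QALY values are carried at full precision and rounded only
at reporting boundaries (whole EUR; five-decimal QALYs; ties away from
zero).  Stochastic checks run at n = 10⁵ cohort records and 10⁴ PSA
draws with 3-Monte-Carlo-SE tolerances; the Markov property tests use
randomised 5-cycle instances against a brute-force scalar loop.  These
sizes keep every stochastic estimate's standard error an order of
magnitude below the quantities being checked while the full suite runs
in a few seconds.

## Known limitations

* The waiting decrement, per-event QALY loss, Gompertz parameters, CVD
  incidence and state utilities are calibrated or conventional values,
  not independently sourced inputs; conclusions that depend on their
  fine structure (rather than the calibrated anchors) should be treated
  accordingly.
* The PSA excludes the Markov model's structural parameters; uncertainty
  enters through the per-event QALY loss only via its base-case value.
* Two strategies only; no efficiency frontier over ≥ 3 options.
* Coverage fractions are inputs; there is no geographic modelling.
* An induced-testing fraction (default 0.15, plausible range 0.10–0.15)
  is stored for sensitivity use but excluded from base outputs, since
  the induced patients are already part of the observed primary-care
  cohort.
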