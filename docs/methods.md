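# Methods

## Model structure

`rrtcea` implements a state-transition cohort model for incident ESRD
patients with states {PD, PD+complication, HD, HD+complication, supportive
care, dead}. Death is absorbing; complication states are within-cycle
sub-states (an episode lasts `complication_months`, default 1, of the year
it occurs in, after which the patient returns to the uncomplicated state of
the current modality). There is no transplantation state and no age/sex
structure. Dialysis arms use one-year cycles; supportive care uses
one-month cycles. Mortality is modality-independent: a six-year registry
schedule of annual death probabilities, extrapolated beyond year six as a
constant hazard (the year-6 value repeats). The default horizon of 22
annual cycles operationalizes a lifetime horizon: residual cohort survival
is below 4 % by then.

## Within-cycle conventions

The ordering of events inside a cycle and the dating of accruals are not
identifiable from aggregate model descriptions, so they are explicit,
documented package choices, fixed once and shared verbatim between the
cohort engine and the patient-level microsimulation:

1. **Switch first.** At cycle start, living patients may switch modality
   (annual probabilities, recurring every year — switching is memoryless,
   not once-per-lifetime). Switchers pay the new modality's initiation cost
   at the moment of switching. Because mortality is identical in all living
   states, applying the switch before or after the death draw yields the
   same occupancy law; switch-first has the advantage of being coherent at
   the individual level (a patient who dies mid-year is costed for the
   modality they entered the year on).
2. **Costs at cycle start.** The year's treatment costs — maintenance,
   expected complication treatment (complication probability × annual
   complication treatment cost), and under the societal perspective the
   household non-medical and indirect annual costs — are charged to
   everyone entering the year and discounted at the cycle-start date.
   Treatment for a year is paid whether or not the patient survives it.
3. **Outcomes at cycle end.** Survivors accrue the year's life-years and
   utility, discounted at the cycle-end date. Deaths contribute nothing in
   their death year. A half-cycle correction (average of start/end
   occupancy, mid-cycle discounting) is available as a setting and off by
   default.
4. **Supportive care counts the death month.** Patients alive at the start
   of a month live, and are costed for, that month even if they die in it,
   so undiscounted life expectancy is the full geometric mean 1/p months
   (p = 0.405 per month). The supportive medical cost (444,400 IDR) is a
   per-month tariff; the household cost (274,881 IDR) is a one-off lifetime
   amount charged at entry. The arm runs until residual living occupancy
   falls below 1e-9 or the horizon is reached.

Conventions 2–4 are calibration choices: the combination of start-of-cycle
cost accrual with end-of-cycle outcome accrual is the convention set under
which the model reproduces the published per-patient results, and the
monthly reading of the supportive-care death probability is forced by the
published 0.21 life-years (1/0.405 months); an annual reading would give
2.5 years. The supportive-care utility is assumed equal to the utility of
dialysis with complication (0.37), as in the source study.

## Outcomes and decision metrics

Headline LY and QALY are reported undiscounted; incremental analysis uses
costs and QALYs discounted at 3 %/year (configurable, applied to both).
The provider perspective includes direct medical costs only; the societal
perspective adds household non-medical and indirect costs. ICERs are
ΔC/ΔE on discounted values, with explicit `dominated` / `dominant` /
`equivalent` flags instead of signed ratios. The frontier routine sorts by
effect, removes strictly dominated options, then removes extendedly
dominated options (a weakly higher incremental ratio below than above
drops the middle point) and reports sequential ICERs along the frontier.
Net monetary benefit is λ·QALY − cost in the active perspective.

## Probabilistic sensitivity analysis

Every parameter is a (mean, SE, family) triplet. Families follow the
source table: Beta for probabilities and utilities, Gamma for costs, fitted
by method of moments (`alpha = m(m(1−m)/se² − 1)`, `shape = (m/se)²`,
`scale = se²/m`), so fitted distributions reproduce the stated moments
exactly. Beta fitting requires `se² < m(1−m)`; infeasible inputs fail at
setup, not per draw. Two complication probabilities carry a Gamma family
in the source table; they are sampled from the fitted Gamma and truncated
to [0, 1], and the validator surfaces a warning for such rows. `se = 0`
marks a parameter as fixed, which makes deterministic runs a special case
of the PSA code path.

A PSA draw samples the full parameter set once and runs all three policies
on it (common random numbers, reducing the variance of incremental
quantities); 1,000 draws by default. The CEAC assigns each draw's vote to
the policy with the highest NMB, splitting ties equally, which keeps the
curve normalized. The default WTP grid is 0–400 million IDR/QALY in
2-million steps; the takeover threshold reported for a policy is the
smallest grid point at which its probability strictly exceeds all others
(grid resolution, ±2 million, bounds the reported threshold's precision).
Identical (seed, draws, parameters) yield bit-identical results.

## Budget impact

The payer projection enrolls `coverage × (prevalence + incidence)` patients
in year 1 and `coverage × incidence` in each later year; each entry cohort
evolves through the cohort engine (modality mix, complications, switch
initiations, and mortality attrition unless disabled). Budgets are
undiscounted direct-medical expenditure, per standard budget-impact
practice. Defaults: prevalence 63,818, incidence 17,913, five years,
coverage scenarios 53 % and 100 % (each scenario holds coverage constant).
The published five-year totals are not an internally consistent target (the
source reports two conflicting sets, neither derivable from its own unit
costs), so the budget module is validated by properties instead: PD-first
strictly below HD-first every year and cumulatively, exact linearity in
coverage at fixed composition, and monotonicity in every unit cost.

## Microsimulation oracle and synthetic survey

The microsimulation samples individual trajectories with exactly the
cohort engine's probabilities, event ordering and accrual dating, so its
sample means are unbiased estimates of the cohort quantities; the test
suite requires agreement within 3 Monte-Carlo standard errors at 100,000
patients, for the default inputs and for randomly drawn parameter sets.
Dialysis events are sampled at year boundaries (times recorded in months);
supportive care is sampled monthly via the geometric death-month law.

The synthetic questionnaire generator draws per-patient household costs,
income loss and utilities from the moment-matched input distributions,
using the published standard error as the patient-level spread — the study
reports SEs only, so patient-level dispersion is not recoverable; this
choice makes re-estimation (sample mean, sample SD) a clean round trip to
the published (mean, SE) table. It emulates arm sizes and column structure
only, not the real questionnaire's items or demographics. Consequently,
passing tests show internal consistency of the model chain, not fidelity
of the inputs to any patient population.

## Numerical choices and limitations

- Occupancy conservation is asserted at every cycle (tolerance 1e-9);
  violations raise instead of propagating.
- Currency is kept in raw IDR internally; human-readable summaries print
  millions (per-patient) or trillions (budgets) with one decimal.
- Problem sizes throughout (22 annual cycles, 1,000 PSA draws, 100,000
  microsimulation patients) are the package defaults and run in seconds.
- The model inherits the source study's strong assumptions: equal PD/HD
  survival, a single national cost schedule, constant hazards beyond year
  six, and an expert-opinion supportive-care death rate. The published
  provider-perspective lifetime costs order PD-first above HD-first, which
  is not reproducible from the published unit costs under equal survival
  (HD maintenance is ~21.5 M IDR/year dearer and the cohort drifts toward
  HD under either policy); this package reports the internally consistent
  provider totals instead.
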