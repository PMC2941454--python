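# Methods

## Model structure

The cohort engine (`crbsi_cea.cohort`) is a discrete-time Markov model
with daily cycles in hospital and annual cycles after discharge.
States:

- `cath{d}` — catheterised ICU day *d* (tunnel states, *d* = 1..30, so
  hazards can vary with catheter duration);
- `crbsi{d}` — infected ICU track, day-indexed like the catheter
  track;
- `icu{j}` — post-dwell ICU tail (default 1 day);
- `ward{w}` — general ward stay (default 7 days);
- `post{y}` — post-discharge years 1–15 with published annual death
  probabilities;
- `longterm` — age-banded background mortality to a hard cap at age
  100 (remaining mass dies at the first year boundary at or past the
  cap, with no accrual in that year);
- `dead` — absorbing.

Every transition row sums to one; occupancy vectors are checked to
1e−9 and the dead fraction is non-decreasing (tested properties).

### Within-day event scheme

Within an in-hospital day, death is checked first. Among survivors,
CR-BSI onset (probability = band hazard × strategy relative risk) and
dwell end (the discrete Weibull removal hazard
[S(d−1) − S(d)]/S(d−1), S(t) = exp(−(t/scale)^shape), forced to 1 at
day 30) are **conditionally independent**. Infection is a *marker*
event: it triggers the episode's consequences but never changes the
dwell clock — the infected track `crbsi{d}` carries exactly the same
day-indexed death and dwell-end hazards as `cath{d}`, minus the
infection risk (no second episodes).

This is a deliberate design choice. A strictly sequential
competing-risk ordering (death → infection → removal) silently couples
infection with exposure time: an infection would cancel that day's
removal check and hold the patient in the high-hazard ICU states
longer, roughly doubling deaths per infection through extra exposure
rather than through the attributable effect. Under the marker scheme
the entire survival effect of an episode is the attributable absolute
mortality increase, Δ = (RR − 1) × hospital cumulative risk = 0.06 ×
0.161 ≈ 0.0097, applied once at episode entry. (The net effect is
slightly below Δ because a patient killed by the episode forgoes a
~14% baseline in-hospital death risk they would otherwise have faced.)

Of the two published candidates for anchoring Δ, the ICU (0.098) and
hospital (0.161) cumulative risks, the hospital figure is used: it is
the one consistent with an absolute increase "just under 1%".

### Episode consequences

Each episode adds, at the infection cycle's discount factor:

- diagnostics ($101.70) and treatment ($591.30) for every infected
  patient;
- 2.41 excess ICU days and 7.54 excess ward days, as deterministic
  bed-day/cost lumps, for patients surviving the attributable-death
  draw. Excess days shift where time is lived, not how much of it, and
  the early post-discharge utility equals the in-hospital utility
  (0.66), so the episode carries no direct QALY decrement; infection
  affects QALYs only through mortality.

## Calibration

Three structural inputs are not published and are treated as derived,
never configured:

| quantity | target | solver |
|---|---|---|
| Weibull removal scale | baseline cumulative CR-BSI risk = 2.5% | bisection (brentq) |
| daily ICU death hazard | cumulative ICU mortality = 9.8% | bisection |
| daily ward death hazard | cumulative hospital mortality = 16.1% | bisection |

The Weibull shape is fixed at 1.5 (mild wear-in of removal rates; with
the calibrated scale ≈ 5.22 the mean dwell is ≈ 4.7 days). The three
targets interact weakly (deaths censor infection opportunities and
vice versa), so the bisections repeat to a joint fixed point, residual
tolerance 1e−6, typically converging in two or three outer rounds.
Calibration is idempotent to within that tolerance. An unreachable
target (e.g. a degenerate 0% or an absurd 90% infection target)
raises with the bracket and residuals. The calibrated daily hazards
come out at ≈ 0.0167 (ICU) and ≈ 0.0103 (ward) per day.

Baseline uninfected lengths of stay are likewise unpublished; the ICU
stay is catheter dwell + a 1-day tail and the ward stay is 7 days.
These choices set the *level* of per-patient cost, but every decision
quantity is a *difference* between strategies, which the calibrated
cumulative risks pin down; the threshold results are insensitive to
the stay structure (verified by the linearity and microsimulation
tests).

## Outcomes and discounting

Per patient and perspective (`crbsi_cea.outcomes`):

- catheter consumable cost at insertion, undiscounted ($0 uncoated,
  $11.64 CH/SSD, $59.36 MR);
- every occupied bed-day at the perspective's valuation (full $3,021
  ICU / $843 ward, or variable $362/$101), discounted at
  (1+r)^(−t) with r = 3%/year and t measured from ICU admission
  (mid-day within the daily phase);
- QALYs at 0.66 per in-hospital day (1/365.25 year each); post
  discharge 0.66 for the first six months, then age-banded population
  norms (0.80 to 59, 0.79 for 60s, 0.75 for 70s, 0.66 from 80), ages
  outside the published bands taking the nearest band; age advances
  with calendar time from 62.7.
- annual cycles accrue with a half-cycle correction (deaths credit
  half the year); the correction is a switch
  (`half_cycle_correction`) and daily cycles are short enough not to
  need one.

After the daily phase the discharged mass is pooled at its
mass-weighted mean discharge time (≈ day 13) before the annual phase
starts. The spread of discharge times is under six weeks, so pooling
the discount clock is exact to first order; the microsimulation, which
keeps exact per-patient clocks, agrees with the cohort engine within
Monte-Carlo error at n = 200,000 (tested at 3 SE).

## Decision layer

`crbsi_cea.cea` implements standard incremental CEA (strict and
extended dominance with ICERs along the efficiency frontier; ties
within $0.01 / 1e−9 QALY resolved toward the incumbent: current
practice, then coated catheters, then the bundle) and the threshold
machinery. The bundle's nationwide 18-month budget X enters as
X / 13,635 per patient (13,635 = 53,470 annual admissions × 17%
catheterised × 1.5 years), making NMB linear in X; thresholds are
closed-form with a permanent bisection cross-check (agreement under
$1 is a tested invariant). Negative solutions are reported as 0 with
a `never_admissible` flag.

Minimum effectiveness inverts the threshold: the largest relative risk
at which a $1 bundle still reaches NMB parity, solved by bisection on
the RR (the threshold is strictly decreasing in RR). "Effective
elimination" of infection is operationalised as RR = 0.001.

Frontier maps report, per RR, a cost-saving boundary (cost parity at
λ = 0) and a cost-effective boundary (NMB parity at the perspective's
λ). Cost-saving is defined as *cheaper and preferred*: where the
bundle's RR exceeds the best comparator's (fewer QALYs), the
λ-weighted parity is the binding constraint, so the cost-saving
boundary is the minimum of the two parities, clamped at zero. This
keeps cost-saving ⊆ cost-effective at every RR.

## Microsimulation and synthetic registries

`crbsi_cea.microsim` samples individual trajectories from the same
event functions the cohort engine uses (`crbsi_cea.events` is the
single source of truth; a test enumerates all catheter days and
compares the cohort's transition rows with the simulator's raw event
probabilities exactly). Randomness is one Philox counter-based
substream per patient — patient *i*'s block of uniforms is independent
of how many patients are simulated — and summaries are accumulated
streaming over fixed-size chunks.

`generate_registry` emulates the kind of quasi-experimental catheter
registry the model's hazards would be estimated from: one row per
patient with age (truncated normal, sd 17.2 on [18, 100], location
shifted so the truncated mean is 62.7), catheter end day and reason,
infection day, death phase and bed-day/cost/QALY outcomes. For the
cohort-agreement checks the simulation uses the cohort's fixed mean
age; sampling ages changes mean QALYs slightly because utility is a
step function of age (bounded at 5% in a test). What the generator
does *not* emulate: organism mix, severity-dependent consequences,
multiple catheterisations, inter-unit heterogeneity, or secular
trends — so passing recovery tests shows internal consistency of the
estimation pipeline, not robustness to real-data messiness.

`estimate_parameters` re-enacts the estimation step on a registry:
banded infection hazards as events per at-risk catheter-day (the death
day is excluded from at-risk time because the death check precedes the
infection check; bands with under 5 events are flagged), and an
interval-censored Weibull MLE for the dwell (removal on day *d* lies
in (d−1, d]; infections and in-catheter deaths censor at d−1, the
forced removal at day 30 censors at day 29). Shape recovery is within
10% at n = 50,000 (tested). A closure test runs
generate → estimate → calibrate (mortality only) → cohort and checks
the fitted model reproduces the generating 2.5% infection risk within
Monte-Carlo error.

## Configuration

A single YAML file (schema_version 1) mirrors the dataclasses in
`crbsi_cea.parameters`; all defaults are baked in, so the package runs
with zero files. Unknown fields are rejected by name;
`validate_parameters` returns the full violation list as data.
Currency is fixed 2006 AUD (inputs were already price-adjusted; no CPI
machinery). The calibrated hazards round-trip through the file but the
removal scale is recalibrated on every CLI run regardless — the scale
is a derived quantity, and trusting a stale value after editing, say,
the infection bands would silently break the 2.5% constraint.

## Numerical choices

- Bisections use `scipy.optimize.brentq` (xtol 1e−12 for calibration,
  1e−7 on RR for minimum effectiveness, well inside the reported
  precision).
- Cohort mass below 1e−15 is dropped; occupancy sums are preserved to
  1e−9 over the full horizon.
- The daily phase is bounded by construction (dwell forced to end at
  day 30, fixed tail and ward lengths); a failure to empty the
  hospital states raises with the cycle index, as does any NaN
  occupancy.
- Problem sizes in the test suite: microsimulation agreement at
  n = 200,000 (≈ 3 SE ≈ 0.3% on QALYs), registry estimation at
  n = 50,000, property grids at 5–20 RR points — chosen so the whole
  suite exercises every published quantity in well under a minute of
  compute.

## Known limitations

- No catheter colonisation state, no multiple catheterisations per
  patient, no organism- or severity-specific pathways, and no
  probabilistic sensitivity analysis: the model is deterministic with
  point estimates, matching its threshold-analysis purpose.
- The ward utility weight is not separately published; it defaults to
  the ICU value (0.66) and is configurable.
- The infected track inherits the catheter track's dwell hazards; if
  real CR-BSI prolongs the *hazard-bearing* ICU stay beyond the 2.41
  modelled excess days, the attributable mortality here understates
  the total effect.
- Bundle implementation cost is a scalar; its resource composition is
  out of scope by design.
- Thresholds scale linearly with the predicted catheterisation count
  and are anchored to a 2.5% baseline infection risk; settings with
  materially different baseline risk shift every threshold in the
  same direction.
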