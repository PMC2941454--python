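# crbsi-cea

Cost-effectiveness modelling of central venous catheter (CVC)
infection control in Australian Level III intensive care units.

Catheter-related bloodstream infections (CR-BSI) are largely
preventable, and several strategies compete for the same budget:
staying with current practice (uncoated catheters, no bundled care),
switching to antimicrobial-coated catheters
(chlorhexidine/silver-sulfadiazine, CH/SSD, or minocycline/rifampicin,
MR), or implementing a catheter care *bundle* (hand hygiene,
chlorhexidine antisepsis, barrier precautions, site choice, prompt
removal, plus the education and monitoring needed to make it stick).
The bundle's consumables are cheap but its implementation cost is
genuinely unknown, so the question this package answers is not "what
is the bundle's ICER" but "**how much is a bundle allowed to cost**
before an alternative becomes the better buy?"

The package is aimed at health-economics and infection-control
researchers who want a transparent, testable re-implementation of this
decision model: a deterministic Markov cohort engine, a patient-level
microsimulation that acts as its Monte-Carlo oracle and synthetic-data
generator, and the threshold machinery on top.

## The model

A unit cohort of catheterised ICU patients (mean age 62.7) moves
through daily-cycle tunnel states while in hospital and annual cycles
afterwards:

- catheter-day states *d* = 1..30 with a stepwise daily CR-BSI
  probability (0.004 for days 1–5, 0.009 for 6–15, 0.020 for 16–30),
  scaled by a strategy's relative risk *r*;
- a Weibull dwell-end (catheter removal) process, forced at day 30;
- an infected track with identical dwell hazards (a CR-BSI changes
  survival only through its attributable mortality, Δ = (RR−1) × 0.161
  ≈ 0.0097 with RR = 1.06, and adds episode costs plus 2.41 excess ICU
  and 7.54 excess ward days for episode survivors);
- a 1-day post-dwell ICU tail and a 7-day ward stay, with daily death
  hazards calibrated so cumulative mortality is 9.8% in ICU and 16.1%
  by discharge;
- fifteen post-discharge years with published annual death
  probabilities, then age-banded population rates to an age cap of 100.

QALYs use utility 0.66 in hospital and for six months after discharge,
then age-banded population norms; costs and QALYs are discounted at 3%
per year (2006 AUD throughout). Three unpublished inputs — the Weibull
scale and the two daily death hazards — are recovered by bisection
against the published cumulative constraints (baseline infection risk
2.5%, mortality 9.8%/16.1%).

For strategies with per-patient cost *C*, QALYs *Q* and a
willingness-to-pay λ, decisions use net monetary benefit,
NMB = λ·Q − C. The bundle (relative risk 0.34, unknown nationwide
18-month budget *X* spread over 13,635 predicted catheterisations) is
cost-effective while

NMB_bundle(X) ≥ max over comparators of NMB_comparator,

which is linear in *X*, so the threshold budget is closed-form (and
cross-checked by bisection). Four perspectives are built in: baseline
(λ = $64,000/QALY, bed-days at $3,021 ICU / $843 ward), no value on
QALYs (λ = 0), variable bed-day values ($362/$101), and cash-savings
only (λ = 0 and variable values).

## Worked example

Maximum nationwide 18-month bundle budget against current practice
only, at the bundle's trial effectiveness (relative risk 0.34):

```sh
$ crbsi-cea threshold --comparison pairwise --rr 0.34 --out-dir results
calibrating model (removal scale, daily death hazards)...
threshold nationwide $4,278,340 (per ICU $93,007), best comparator current_practice
```

A decision-maker who rejects antimicrobial catheters can pay up to
about $4.28M nationally (≈ $93k per ICU) for bundle implementation
before staying with current practice is the better use of funds. The
full four-perspective table:

```sh
$ crbsi-cea scenarios --out-dir results
      baseline  pairwise: $4,278,340 (min RR 1.000)
      baseline three_way: $2,247,540 (min RR 0.684)
      baseline  four_way: $1,137,573 (min RR 0.514)
       no_qaly  pairwise: $3,134,728 (min RR 1.000)
       ...
     cash_only  pairwise: $511,822 (min RR 1.000)
```

Reading the baseline rows: once CH/SSD catheters are an acceptable
alternative the admissible bundle budget drops to ≈ $2.25M, and to
≈ $1.14M when MR catheters are also on the table — because the coated
catheters are themselves effective and cheap. The "min RR" column is
the weakest effectiveness at which a near-free ($1) bundle still earns
its place: 0.684 against CH/SSD, ≈ 0.51 against MR. A decision-maker
interested only in cash savings (no value on QALYs or freed bed-day
capacity) should pay at most ≈ $0.51M even against current practice —
infection control is cost-effective long before it is cash-saving.

Per-strategy outcomes and dominance:

```sh
$ crbsi-cea evaluate --out-dir results
mr: cost $23,090, 7.9742 QALYs, on_frontier
chssd: cost $23,137, 7.9736 QALYs, strictly_dominated
current_practice: cost $23,243, 7.9730 QALYs, strictly_dominated
```

Other subcommands: `frontier` (cost-saving / cost-effective /
dominated boundaries per effectiveness level, plot-ready CSV),
`simulate` (patient-level Monte-Carlo summary), `generate` (synthetic
patient registry), `calibrate` (write the calibrated configuration).
All accept `--config` with a YAML parameter file; every run writes a
`manifest.json` with the package version, configuration hash and
output list.

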