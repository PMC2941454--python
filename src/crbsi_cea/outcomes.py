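"""Expected discounted costs and QALYs per catheterised patient.

A cohort trace is turned into a :class:`StrategyOutcome` under a
decision-maker perspective.  Costing rules: the catheter consumable is
incurred at insertion (undiscounted); every occupied bed-day is valued
at the perspective's ICU/ward rate; a CR-BSI episode adds diagnostics
and treatment for all infected patients and 2.41 ICU + 7.54 ward excess
bed-days for episode survivors, discounted at the episode cycle.  QALYs
accrue per day in hospital (utility 0.66) and per post-discharge year
(0.66 for the first six months, age-banded population norms after),
with an optional half-cycle correction on annual cycles.

The excess stay shifts where time is lived, not how much of it, and the
early post-discharge utility equals the in-hospital utility, so the
episode carries no direct QALY decrement — infection affects QALYs only
through its mortality increase.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import CohortTrace, run_cohort
from .parameters import CostInputs, ModelParameters, Perspective, Strategy

__all__ = ["StrategyOutcome", "discount_factor", "crbsi_episode_cost", "evaluate_strategy"]


def discount_factor(elapsed: float, rate: float) -> float:
    """(1 + rate)^(-elapsed) for elapsed years >= 0."""
    if elapsed < 0:
        raise ValueError(f"elapsed must be >= 0, got {elapsed}")
    return (1.0 + rate) ** (-elapsed)


def crbsi_episode_cost(costs: CostInputs, perspective: Perspective) -> float:
    """Undiscounted cost of one CR-BSI episode under a perspective.

    Excess ICU and ward days at the perspective's bed-day valuation,
    plus diagnostics and treatment.
    """
    return (
        costs.excess_icu_days * perspective.icu_rate(costs)
        + costs.excess_ward_days * perspective.ward_rate(costs)
        + costs.diagnostics
        + costs.treatment
    )


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-patient expected results for one strategy under one perspective.

    ``expected_cost_per_patient`` excludes any nationwide program cost;
    that enters only at the net-monetary-benefit stage.
    """

    strategy: str
    perspective: str
    expected_cost_per_patient: float
    expected_qalys_per_patient: float
    expected_infections_per_patient: float
    expected_icu_bed_days: float
    expected_ward_bed_days: float


def evaluate_strategy(
    p: ModelParameters,
    s: Strategy,
    persp: Perspective,
    *,
    trace: CohortTrace | None = None,
) -> StrategyOutcome:
    """Run the cohort for ``s`` and accumulate discounted costs and QALYs.

    Deterministic.  A precomputed ``trace`` may be supplied (the trace
    depends only on the strategy's relative risk, not the perspective).
    """
    if trace is None:
        trace = run_cohort(p, s)
    c = p.costs
    u = p.utilities
    rate = persp.discount_rate
    icu_rate = persp.icu_rate(c)
    ward_rate = persp.ward_rate(c)
    fixed_episode = c.diagnostics + c.treatment
    excess = c.excess_icu_days * icu_rate + c.excess_ward_days * ward_rate

    cost = s.per_catheter_cost
    qalys = 0.0
    for row in trace.daily.itertuples():
        df = discount_factor(row.t_mid, rate)
        cost += df * (
            row.icu_days * icu_rate
            + row.ward_days * ward_rate
            + row.new_infections * fixed_episode
            + row.surviving_infections * excess
        )
        qalys += df * (row.icu_days * u.icu_and_early_postdischarge + row.ward_days * u.ward) / 365.25

    for row in trace.annual.itertuples():
        df = discount_factor(row.t_mid, rate)
        if row.year == 1:
            # first six months at the post-ICU utility, remainder at the norm
            util = 0.5 * u.icu_and_early_postdischarge + 0.5 * u.norm(row.age_mid)
        else:
            util = u.norm(row.age_mid)
        alive = 0.5 * (row.alive_start + row.alive_end) if p.half_cycle_correction else row.alive_end
        qalys += df * alive * util

    return StrategyOutcome(
        strategy=s.name,
        perspective=persp.name,
        expected_cost_per_patient=cost,
        expected_qalys_per_patient=qalys,
        expected_infections_per_patient=trace.cumulative_infection,
        expected_icu_bed_days=trace.daily["icu_days"].sum() + c.excess_icu_days * trace.surviving_infection,
        expected_ward_bed_days=trace.daily["ward_days"].sum() + c.excess_ward_days * trace.surviving_infection,
    )
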