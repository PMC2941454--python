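"""Incremental cost-effectiveness analysis and threshold machinery.

The care bundle's implementation cost is unknown, so instead of a
single ICER the package solves threshold questions: the maximum
nationwide 18-month budget X at which the bundle's net monetary benefit
(NMB = wtp x QALYs - cost) still matches the best comparator's, the
minimum effectiveness (relative risk of CR-BSI) at which a near-free
bundle stays cost-effective, and the cost-saving / cost-effective /
dominated regions of the (effectiveness, cost) plane.

NMB is linear in X, so thresholds have a closed form; a bisection root
is always computed alongside as a cross-check and reported in the
solver diagnostics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cohort import run_cohort
from .outcomes import StrategyOutcome, evaluate_strategy
from .parameters import PERSPECTIVES, ModelParameters, Perspective, ScaleAssumptions, Strategy

__all__ = [
    "ComparisonSet",
    "ThresholdResult",
    "FrontierMap",
    "RankedStrategy",
    "comparison_set",
    "COMPARISON_LABELS",
    "nmb",
    "dominance_ranking",
    "predicted_catheterisations",
    "bundle_cost_threshold",
    "minimum_effectiveness",
    "frontier",
    "scenario_table",
]

COMPARISON_LABELS = ("pairwise", "three_way", "four_way")

# tie-break preference: incumbent first, then catheters, then the bundle
_PREFERENCE = ("current_practice", "chssd", "mr", "bundle")
_TOL_COST = 0.01
_TOL_QALY = 1e-9


def predicted_catheterisations(scale: ScaleAssumptions) -> int:
    """Catheterisations expected nationwide over the program horizon."""
    return round(scale.annual_admissions * scale.catheterised_fraction * scale.horizon_years)


def nmb(o: StrategyOutcome, wtp: float, program_cost_per_patient: float = 0.0) -> float:
    """Net monetary benefit per patient at willingness to pay ``wtp``."""
    return wtp * o.expected_qalys_per_patient - (o.expected_cost_per_patient + program_cost_per_patient)


@dataclass(frozen=True)
class ComparisonSet:
    """The strategies a decision-maker is prepared to consider.

    ``pairwise`` = {current practice, bundle}; ``three_way`` adds CH/SSD
    catheters; ``four_way`` adds MR catheters.  The bundle appears
    exactly once and current practice is always present.
    """

    label: str
    comparators: tuple[Strategy, ...]
    bundle: Strategy

    def __post_init__(self):
        names = [s.name for s in self.comparators] + [self.bundle.name]
        if names.count(self.bundle.name) != 1:
            raise ValueError("bundle must appear exactly once in a comparison set")
        if not any(s.rr_crbsi == 1.0 for s in self.comparators):
            raise ValueError("current practice (rr=1) must be among the comparators")


def comparison_set(label: str, p: ModelParameters) -> ComparisonSet:
    members = {
        "pairwise": ("current_practice",),
        "three_way": ("current_practice", "chssd"),
        "four_way": ("current_practice", "chssd", "mr"),
    }
    if label not in members:
        raise ValueError(f"unknown comparison set {label!r}; expected one of {COMPARISON_LABELS}")
    return ComparisonSet(
        label=label,
        comparators=tuple(p.strategy(n) for n in members[label]),
        bundle=p.strategy("bundle"),
    )


# ---------------------------------------------------------------------------
# dominance

@dataclass(frozen=True)
class RankedStrategy:
    name: str
    cost: float
    qalys: float
    status: str  # on_frontier | strictly_dominated | extended_dominated
    icer: float | None  # vs previous frontier member; None for the cheapest


def _pref_index(name: str) -> int:
    try:
        return _PREFERENCE.index(name)
    except ValueError:
        return len(_PREFERENCE)


def dominance_ranking(outcomes: Iterable[StrategyOutcome]) -> list[RankedStrategy]:
    """Standard incremental CEA ranking with dominance flags.

    Strategies are sorted by cost; a strategy is strictly dominated if a
    cheaper (or tied, preference-ordered) one yields at least as many
    QALYs, and extended dominated if it is bypassed by a steeper ICER
    further up the frontier.  Survivors carry ICERs vs the previous
    frontier member.  Ties within $0.01 / 1e-9 QALY go to the incumbent.
    """
    entries = [
        (o.strategy, o.expected_cost_per_patient, o.expected_qalys_per_patient)
        for o in outcomes
    ]
    if len(entries) < 2:
        return [RankedStrategy(n, c, q, "on_frontier", None) for n, c, q in entries]
    entries.sort(key=lambda e: (e[1], _pref_index(e[0])))

    status = {}
    for i, (ni, ci, qi) in enumerate(entries):
        dominated = False
        for j, (nj, cj, qj) in enumerate(entries):
            if i == j:
                continue
            cheaper = cj < ci - _TOL_COST or (abs(cj - ci) <= _TOL_COST and _pref_index(nj) < _pref_index(ni))
            if cheaper and qj >= qi - _TOL_QALY:
                dominated = True
                break
        status[ni] = "strictly_dominated" if dominated else "on_frontier"

    frontier = [e for e in entries if status[e[0]] == "on_frontier"]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for k in range(1, len(frontier) - 1):
            n0, c0, q0 = frontier[k - 1]
            nk, ck, qk = frontier[k]
            n2, c2, q2 = frontier[k + 1]
            icer_k = (ck - c0) / max(qk - q0, _TOL_QALY)
            icer_next = (c2 - ck) / max(q2 - qk, _TOL_QALY)
            if icer_k >= icer_next:
                status[nk] = "extended_dominated"
                frontier.pop(k)
                changed = True
                break

    icers: dict[str, float | None] = {}
    for k, (nk, ck, qk) in enumerate(frontier):
        if k == 0:
            icers[nk] = None
        else:
            _, c0, q0 = frontier[k - 1]
            icers[nk] = (ck - c0) / max(qk - q0, _TOL_QALY)

    return [RankedStrategy(n, c, q, status[n], icers.get(n)) for n, c, q in entries]


# ---------------------------------------------------------------------------
# thresholds

class _Evaluator:
    """Memoises cohort traces (keyed by rr) and outcomes within one analysis."""

    def __init__(self, p: ModelParameters):
        self.p = p
        self._traces: dict[float, object] = {}
        self._outcomes: dict[tuple, StrategyOutcome] = {}

    def outcome(self, s: Strategy, persp: Perspective) -> StrategyOutcome:
        key = (s.rr_crbsi, s.per_catheter_cost, persp.name, persp.wtp_per_qaly,
               persp.bed_day_valuation, persp.discount_rate)
        if key not in self._outcomes:
            tr = self._traces.get(s.rr_crbsi)
            if tr is None:
                tr = self._traces[s.rr_crbsi] = run_cohort(self.p, s)
            self._outcomes[key] = evaluate_strategy(self.p, s, persp, trace=tr)
        return self._outcomes[key]

    def best_comparator(self, cs: ComparisonSet, persp: Perspective) -> tuple[str, float]:
        """(name, per-patient NMB) of the NMB-maximising comparator."""
        if not cs.comparators:
            raise ValueError("empty comparator set")
        best_name, best_nmb = None, -np.inf
        for s in sorted(cs.comparators, key=lambda s: _pref_index(s.name)):
            v = nmb(self.outcome(s, persp), persp.wtp_per_qaly)
            if v > best_nmb + 1e-12:
                best_name, best_nmb = s.name, v
        return best_name, best_nmb


@dataclass(frozen=True)
class ThresholdResult:
    """Solved maximum bundle cost under one comparison and perspective.

    ``threshold_cost_nationwide`` is the 18-month Australia-wide budget,
    clamped at zero; a negative closed-form solution sets
    ``never_admissible`` and is kept in ``raw_nationwide``.
    ``closed_form``/``bisection``/``gap`` are solver diagnostics.
    """

    comparison: str
    perspective: str
    rr_bundle: float
    threshold_cost_nationwide: float
    threshold_cost_per_icu: float
    best_comparator: str
    never_admissible: bool
    raw_nationwide: float
    closed_form: float
    bisection: float
    gap: float
    n_catheterisations: int


def bundle_cost_threshold(
    cs: ComparisonSet,
    persp: Perspective,
    rr_bundle: float,
    p: ModelParameters,
    *,
    _ev: _Evaluator | None = None,
) -> ThresholdResult:
    """Maximum nationwide bundle cost X with NMB(bundle) >= best comparator.

    The per-patient program cost is X divided by the predicted
    catheterisations, so NMB is linear in X and the parity point is
    closed-form; a brentq root of the same parity equation is reported
    as a cross-check (they agree to well under $1).
    """
    if not (0.0 < rr_bundle <= 1.0):
        raise ValueError(f"rr_bundle must be in (0,1], got {rr_bundle}")
    ev = _ev or _Evaluator(p)
    n = predicted_catheterisations(p.scale)
    bundle = dataclasses.replace(cs.bundle, rr_crbsi=rr_bundle)
    ob = ev.outcome(bundle, persp)
    best_name, best_nmb = ev.best_comparator(cs, persp)

    per_patient = nmb(ob, persp.wtp_per_qaly) - best_nmb
    closed = per_patient * n

    def parity(x: float) -> float:
        return nmb(ob, persp.wtp_per_qaly, x / n) - best_nmb

    lo, hi = closed - 1e6, closed + 1e6
    root = brentq(parity, lo, hi, xtol=1e-9)

    clamped = max(closed, 0.0)
    return ThresholdResult(
        comparison=cs.label,
        perspective=persp.name,
        rr_bundle=rr_bundle,
        threshold_cost_nationwide=clamped,
        threshold_cost_per_icu=clamped / p.scale.n_icus,
        best_comparator=best_name,
        never_admissible=closed <= 0.0,
        raw_nationwide=closed,
        closed_form=closed,
        bisection=root,
        gap=abs(closed - root),
        n_catheterisations=n,
    )


def minimum_effectiveness(
    cs: ComparisonSet,
    persp: Perspective,
    p: ModelParameters,
    *,
    min_cost: float = 1.0,
    _ev: _Evaluator | None = None,
) -> float:
    """Largest bundle RR at which the cost threshold is at least ``min_cost``.

    Solved by bisection on the RR; the threshold is strictly decreasing
    in RR (a less effective bundle can justify less spending).
    """
    ev = _ev or _Evaluator(p)

    def g(rr: float) -> float:
        return bundle_cost_threshold(cs, persp, rr, p, _ev=ev).raw_nationwide - min_cost

    lo = 1e-6
    if g(lo) < 0:
        return 0.0
    if g(1.0) >= 0:
        return 1.0
    return brentq(g, lo, 1.0, xtol=1e-7)


# ---------------------------------------------------------------------------
# frontier

@dataclass
class FrontierMap:
    """Cost/effectiveness boundaries of the bundle decision plane.

    ``grid`` holds, per RR, the cost-saving boundary (NMB parity at
    wtp 0 with the perspective's bed-day valuation), the cost-effective
    boundary (parity at the perspective's wtp) and the preferred
    comparator should the bundle be dominated.  Boundaries are clamped
    at zero.  :meth:`classify` recomputes the boundaries exactly at any
    RR rather than interpolating the grid.
    """

    comparison: str
    perspective: str
    grid: pd.DataFrame
    _p: ModelParameters = field(repr=False)
    _persp: Perspective = field(repr=False)
    _ev: _Evaluator = field(repr=False)

    def classify(self, rr: float, nationwide_cost: float) -> str:
        cs = comparison_set(self.comparison, self._p)
        persp = self._persp
        saving = bundle_cost_threshold(cs, _at_wtp(persp, 0.0), rr, self._p, _ev=self._ev)
        effective = bundle_cost_threshold(cs, persp, rr, self._p, _ev=self._ev)
        cs_bound, ce_bound = _frontier_bounds(saving, effective)
        if nationwide_cost <= cs_bound:
            return "cost_saving"
        if nationwide_cost <= ce_bound:
            return "cost_effective"
        return "dominated"


def _frontier_bounds(saving: ThresholdResult, effective: ThresholdResult) -> tuple[float, float]:
    """(cost-saving, cost-effective) boundaries, clamped at zero.

    Cost-saving means the bundle both reduces total costs and is the
    NMB-preferred option, so its boundary cannot exceed the
    cost-effective one: where the bundle yields fewer QALYs than the
    best comparator (RR above the comparator's), the wtp-weighted
    parity is the binding constraint.
    """
    ce = max(effective.raw_nationwide, 0.0)
    cs = max(min(saving.raw_nationwide, effective.raw_nationwide), 0.0)
    return cs, ce


def _at_wtp(persp: Perspective, wtp: float) -> Perspective:
    return dataclasses.replace(persp, name=f"{persp.name}@wtp={wtp:g}", wtp_per_qaly=wtp)


def frontier(
    cs: ComparisonSet,
    persp: Perspective,
    rr_grid: Sequence[float],
    p: ModelParameters,
) -> FrontierMap:
    """Boundary points of the cost-saving / cost-effective / dominated regions."""
    ev = _Evaluator(p)
    rows = []
    persp0 = _at_wtp(persp, 0.0)
    for rr in rr_grid:
        sav = bundle_cost_threshold(cs, persp0, rr, p, _ev=ev)
        eff = bundle_cost_threshold(cs, persp, rr, p, _ev=ev)
        cs_bound, ce_bound = _frontier_bounds(sav, eff)
        rows.append({
            "rr": rr,
            "cost_saving_boundary": cs_bound,
            "cost_effective_boundary": ce_bound,
            "preferred_comparator": eff.best_comparator,
        })
    return FrontierMap(cs.label, persp.name, pd.DataFrame(rows), p, persp, ev)


# ---------------------------------------------------------------------------
# the four-perspective scenario table

def scenario_table(
    p: ModelParameters,
    *,
    rr_headline: float = 0.34,
    rr_eliminate: float = 0.001,
    comparisons: Sequence[str] = COMPARISON_LABELS,
) -> pd.DataFrame:
    """Thresholds under the four decision-maker perspectives.

    For each perspective (baseline; no value on QALYs; variable bed-day
    values; cash-savings only) and comparison set, reports the
    nationwide threshold at the headline RR and under effective
    elimination of infection, the minimum effectiveness at a $1 budget,
    and the best comparator.
    """
    ev = _Evaluator(p)
    rows = []
    for persp in p.perspectives:
        pname = persp.name
        for label in comparisons:
            cs = comparison_set(label, p)
            head = bundle_cost_threshold(cs, persp, rr_headline, p, _ev=ev)
            elim = bundle_cost_threshold(cs, persp, rr_eliminate, p, _ev=ev)
            min_rr = minimum_effectiveness(cs, persp, p, _ev=ev)
            rows.append({
                "perspective": pname,
                "wtp_per_qaly": persp.wtp_per_qaly,
                "icu_bed_day_value": persp.icu_rate(p.costs),
                "ward_bed_day_value": persp.ward_rate(p.costs),
                "comparison": label,
                "rr_headline": rr_headline,
                "threshold_nationwide": head.threshold_cost_nationwide,
                "threshold_per_icu": head.threshold_cost_per_icu,
                "threshold_eliminate_nationwide": elim.threshold_cost_nationwide,
                "minimum_effectiveness_rr": min_rr,
                "best_comparator": head.best_comparator,
            })
    return pd.DataFrame(rows)
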