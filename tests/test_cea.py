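import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crbsi_cea import (
    PERSPECTIVES,
    ScaleAssumptions,
    StrategyOutcome,
    bundle_cost_threshold,
    comparison_set,
    dominance_ranking,
    evaluate_strategy,
    frontier,
    minimum_effectiveness,
    nmb,
    predicted_catheterisations,
    scenario_table,
)


def _outcome(name, cost, qalys):
    return StrategyOutcome(name, "test", cost, qalys, 0.01, 5.0, 6.0)


class TestNmb:
    def test_zero_wtp_is_cost_minimisation(self):
        o = _outcome("a", 1234.0, 5.0)
        assert nmb(o, 0.0) == -1234.0
        assert nmb(o, 0.0, program_cost_per_patient=100.0) == -1334.0

    def test_known_difference(self):
        a = _outcome("a", 1000.0, 1.00)
        b = _outcome("b", 1100.0, 0.99)
        assert nmb(a, 64000.0) - nmb(b, 64000.0) == pytest.approx(740.0)

    def test_equal_outcomes_equal_nmb(self):
        a, b = _outcome("a", 10.0, 2.0), _outcome("b", 10.0, 2.0)
        assert nmb(a, 64000.0) == nmb(b, 64000.0)


class TestPredictedCatheterisations:
    def test_published_scale(self):
        assert predicted_catheterisations(ScaleAssumptions()) == 13635

    @pytest.mark.parametrize(
        "adm,frac,hz,expected",
        [(100, 1.0, 1.0, 100), (0, 0.17, 1.5, 0), (1000, 0.5, 2.0, 1000)],
    )
    def test_simple_products(self, adm, frac, hz, expected):
        sc = ScaleAssumptions(annual_admissions=adm, catheterised_fraction=max(frac, 1e-9), horizon_years=hz)
        assert predicted_catheterisations(sc) == expected


class TestDominance:
    def test_strict_dominance(self):
        ranked = dominance_ranking([_outcome("A", 10.0, 1.0), _outcome("B", 20.0, 0.9)])
        by = {r.name: r for r in ranked}
        assert by["B"].status == "strictly_dominated"
        assert by["A"].status == "on_frontier"

    def test_extended_dominance(self):
        # B's ICER vs A (10000) exceeds C's ICER vs B (1000): B is bypassed
        ranked = dominance_ranking([
            _outcome("A", 0.0, 1.0),
            _outcome("B", 100.0, 1.01),
            _outcome("C", 110.0, 1.02),
        ])
        by = {r.name: r for r in ranked}
        assert by["B"].status == "extended_dominated"
        assert by["C"].status == "on_frontier"
        assert by["C"].icer == pytest.approx(110.0 / 0.02)

    def test_singleton_has_no_flags(self):
        ranked = dominance_ranking([_outcome("A", 5.0, 1.0)])
        assert ranked[0].status == "on_frontier"
        assert ranked[0].icer is None

    def test_chssd_dominated_by_mr_under_defaults(self, params, baseline):
        outcomes = [
            evaluate_strategy(params, params.strategy(n), baseline)
            for n in ("current_practice", "chssd", "mr")
        ]
        by = {r.name: r for r in dominance_ranking(outcomes)}
        assert by["chssd"].status == "strictly_dominated"
        assert by["mr"].status == "on_frontier"

    @given(st.lists(st.tuples(st.floats(0, 1e5), st.floats(0, 20)), min_size=2, max_size=6))
    def test_frontier_icers_increase(self, pts):
        outcomes = [_outcome(f"s{i}", c, q) for i, (c, q) in enumerate(pts)]
        ranked = dominance_ranking(outcomes)
        frontier_icers = [r.icer for r in sorted(ranked, key=lambda r: r.cost)
                          if r.status == "on_frontier" and r.icer is not None]
        assert all(a <= b + 1e-9 for a, b in zip(frontier_icers, frontier_icers[1:]))


class TestThresholds:
    def test_closed_form_matches_bisection_within_a_dollar(self, params, baseline):
        for label in ("pairwise", "three_way", "four_way"):
            r = bundle_cost_threshold(comparison_set(label, params), baseline, 0.34, params)
            assert r.gap < 1.0

    def test_neutral_bundle_threshold_is_zero(self, params, baseline):
        r = bundle_cost_threshold(comparison_set("pairwise", params), baseline, 1.0, params)
        assert r.raw_nationwide == pytest.approx(0.0, abs=1e-6)
        assert r.threshold_cost_nationwide == 0.0
        assert r.never_admissible

    def test_per_icu_is_nationwide_over_units(self, params, baseline):
        r = bundle_cost_threshold(comparison_set("four_way", params), baseline, 0.34, params)
        assert r.threshold_cost_per_icu == pytest.approx(r.threshold_cost_nationwide / 46)

    def test_threshold_monotone_decreasing_in_rr(self, params, baseline):
        cs = comparison_set("pairwise", params)
        xs = [bundle_cost_threshold(cs, baseline, rr, params).raw_nationwide
              for rr in (0.1, 0.34, 0.6, 0.9)]
        assert xs == sorted(xs, reverse=True)

    def test_threshold_monotone_in_comparator_set(self, params, baseline):
        xs = [bundle_cost_threshold(comparison_set(label, params), baseline, 0.34, params).raw_nationwide
              for label in ("pairwise", "three_way", "four_way")]
        assert xs[0] >= xs[1] >= xs[2]

    def test_threshold_linear_in_catheterisations(self, params, baseline):
        cs = comparison_set("pairwise", params)
        r1 = bundle_cost_threshold(cs, baseline, 0.34, params)
        half = dataclasses.replace(
            params, scale=dataclasses.replace(params.scale, annual_admissions=26735))
        r2 = bundle_cost_threshold(comparison_set("pairwise", half), baseline, 0.34, half)
        assert r2.raw_nationwide / r1.raw_nationwide == pytest.approx(
            r2.n_catheterisations / r1.n_catheterisations, rel=1e-9)

    def test_dominated_bundle_reported_never_admissible(self, params, baseline):
        r = bundle_cost_threshold(comparison_set("four_way", params), baseline, 0.95, params)
        assert r.raw_nationwide < 0
        assert r.threshold_cost_nationwide == 0.0
        assert r.never_admissible

    def test_comparator_switch_between_perspectives(self, params):
        cs = comparison_set("four_way", params)
        at_base = bundle_cost_threshold(cs, PERSPECTIVES["baseline"], 0.34, params)
        at_cash = bundle_cost_threshold(cs, PERSPECTIVES["cash_only"], 0.34, params)
        assert at_base.best_comparator == "mr"
        assert at_cash.best_comparator == "chssd"


class TestMinimumEffectiveness:
    def test_pairwise_admits_nearly_any_effect(self, params, baseline):
        rr = minimum_effectiveness(comparison_set("pairwise", params), baseline, params)
        assert rr > 0.999

    def test_decreases_as_comparators_added(self, params, baseline):
        r3 = minimum_effectiveness(comparison_set("three_way", params), baseline, params)
        r4 = minimum_effectiveness(comparison_set("four_way", params), baseline, params)
        assert r4 < r3 < 1.0

    def test_threshold_at_solution_is_about_one_dollar(self, params, baseline):
        cs = comparison_set("three_way", params)
        rr = minimum_effectiveness(cs, baseline, params)
        x = bundle_cost_threshold(cs, baseline, rr, params).raw_nationwide
        assert x == pytest.approx(1.0, abs=5.0)


class TestFrontier:
    def test_boundaries_ordered_and_monotone(self, params, baseline):
        cs = comparison_set("four_way", params)
        fm = frontier(cs, baseline, np.round(np.arange(0.05, 1.0, 0.05), 3), params)
        g = fm.grid
        assert (g["cost_saving_boundary"] <= g["cost_effective_boundary"] + 1e-6).all()
        assert (g["cost_effective_boundary"].diff().dropna() <= 1e-6).all()
        assert (g["cost_saving_boundary"].diff().dropna() <= 1e-6).all()

    def test_classifier_consistent_with_boundaries(self, params, baseline):
        cs = comparison_set("pairwise", params)
        fm = frontier(cs, baseline, [0.34], params)
        row = fm.grid.iloc[0]
        assert fm.classify(0.34, row["cost_saving_boundary"] * 0.5) == "cost_saving"
        mid = 0.5 * (row["cost_saving_boundary"] + row["cost_effective_boundary"])
        assert fm.classify(0.34, mid) == "cost_effective"
        assert fm.classify(0.34, row["cost_effective_boundary"] * 2 + 1) == "dominated"

    def test_mr_preferred_in_dominated_region_at_baseline(self, params, baseline):
        fm = frontier(comparison_set("four_way", params), baseline, [0.3, 0.6, 0.9], params)
        assert (fm.grid["preferred_comparator"] == "mr").all()


@pytest.fixture(scope="module")
def table(params):
    return scenario_table(params)


class TestScenarioTable:
    def test_shape_and_perspectives(self, table):
        assert len(table) == 12
        assert list(table["perspective"].unique()) == ["baseline", "no_qaly", "variable_beds", "cash_only"]
        base = table[table["perspective"] == "baseline"].iloc[0]
        assert (base["wtp_per_qaly"], base["icu_bed_day_value"], base["ward_bed_day_value"]) == (64000, 3021, 843)
        cash = table[table["perspective"] == "cash_only"].iloc[0]
        assert (cash["wtp_per_qaly"], cash["icu_bed_day_value"], cash["ward_bed_day_value"]) == (0, 362, 101)

    def test_dropping_wtp_lowers_every_threshold(self, table):
        for comparison in ("pairwise", "three_way", "four_way"):
            hi = table.query("perspective == 'baseline' and comparison == @comparison")
            lo = table.query("perspective == 'no_qaly' and comparison == @comparison")
            assert lo["threshold_nationwide"].iloc[0] < hi["threshold_nationwide"].iloc[0]
            hi_v = table.query("perspective == 'variable_beds' and comparison == @comparison")
            lo_v = table.query("perspective == 'cash_only' and comparison == @comparison")
            assert lo_v["threshold_nationwide"].iloc[0] < hi_v["threshold_nationwide"].iloc[0]

    def test_elimination_exceeds_headline(self, table):
        assert (table["threshold_eliminate_nationwide"] >= table["threshold_nationwide"]).all()
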