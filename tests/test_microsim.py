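import dataclasses

import numpy as np
import pytest

from crbsi_cea import (
    PERSPECTIVES,
    Strategy,
    calibrate,
    estimate_parameters,
    evaluate_strategy,
    generate_registry,
    run_cohort,
    simulate_cohort,
    simulate_patient,
)
from crbsi_cea.cohort import CycleContext, build_transition_row
from crbsi_cea.events import cath_day_flows
from crbsi_cea.microsim import _patient_rng


@pytest.fixture(scope="module")
def registry(params):
    return generate_registry(20000, 11, params, params.strategy("current_practice"))


class TestDeterminism:
    def test_same_seed_same_patient_path(self, params, baseline):
        s = params.strategy("current_practice")
        p1 = simulate_patient(_patient_rng(7, 3), params, s, baseline, patient_id=3)
        p2 = simulate_patient(_patient_rng(7, 3), params, s, baseline, patient_id=3)
        assert p1 == p2

    def test_same_seed_same_summary(self, params, baseline):
        s = params.strategy("bundle")
        a = simulate_cohort(2000, 42, params, s, baseline)
        b = simulate_cohort(2000, 42, params, s, baseline)
        assert a == b

    def test_substreams_independent_of_n(self, params, baseline):
        # patient i's draws must not depend on how many others are simulated
        s = params.strategy("current_practice")
        small = simulate_cohort(100, 5, params, s, baseline)
        big = simulate_cohort(300, 5, params, s, baseline)
        # chunking must not change which draws a patient consumes
        again = simulate_cohort(100, 5, params, s, baseline, chunk=17)
        for k in small.mean:
            assert small.mean[k] == pytest.approx(again.mean[k], rel=1e-12, abs=1e-12)
        assert big.n == 300

    def test_registry_bytes_identical_across_runs(self, params, tmp_path):
        s = params.strategy("current_practice")
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        generate_registry(500, 9, params, s, path=f1)
        generate_registry(500, 9, params, s, path=f2)
        assert f1.read_bytes() == f2.read_bytes()


class TestDegenerateHazards:
    def test_zero_rr_never_infects(self, params, baseline):
        s = Strategy("none", 1e-12)
        summ = simulate_cohort(3000, 1, params, s, baseline)
        assert summ.mean["infection"] == 0.0

    def test_no_death_hazards_survive_to_age_cap(self, params, baseline):
        p = dataclasses.replace(
            params,
            icu_daily_death=0.0,
            ward_daily_death=0.0,
            mortality=dataclasses.replace(
                params.mortality,
                post_discharge_annual=tuple((a, b, 0.0) for a, b, _ in params.mortality.post_discharge_annual),
                background_annual_by_age=tuple((a, b, 0.0) for a, b, _ in params.mortality.background_annual_by_age),
            ),
        )
        s = Strategy("none", 1e-12)
        path = simulate_patient(_patient_rng(3, 0), p, s, baseline)
        assert not path.infected
        assert path.died and path.death_phase == "post_discharge"  # the hard age cap
        # dies in the first post-discharge year whose start reaches the cap
        assert path.death_year == pytest.approx(p.age_cap - p.scale.cohort_age, abs=2.5)


class TestCohortAgreement:
    def test_means_within_three_se_of_cohort(self, params, baseline):
        s = params.strategy("current_practice")
        o = evaluate_strategy(params, s, baseline)
        summ = simulate_cohort(50000, 1, params, s, baseline)
        for key, val in [
            ("infection", o.expected_infections_per_patient),
            ("cost", o.expected_cost_per_patient),
            ("qalys", o.expected_qalys_per_patient),
            ("icu_days", o.expected_icu_bed_days),
            ("ward_days", o.expected_ward_bed_days),
        ]:
            assert abs(summ.mean[key] - val) < 3 * summ.se[key], key

    def test_death_fractions_match_calibration(self, params, baseline):
        summ = simulate_cohort(50000, 1, params, params.strategy("current_practice"), baseline)
        assert abs(summ.mean["death_icu"] - 0.098) < 3 * summ.se["death_icu"]
        inhosp = summ.mean["death_icu"] + summ.mean["death_ward"]
        se = summ.se["death_icu"] + summ.se["death_ward"]
        assert abs(inhosp - 0.161) < 3 * se

    def test_sampled_ages_stay_close_to_fixed_age_cohort(self, params, baseline):
        # the cohort engine collapses the age distribution to its mean;
        # utility bands make that an approximation, bounded here
        s = params.strategy("current_practice")
        o = evaluate_strategy(params, s, baseline)
        summ = simulate_cohort(20000, 2, params, s, baseline, sample_ages=True)
        assert summ.mean["qalys"] == pytest.approx(o.expected_qalys_per_patient, rel=0.05)
        assert summ.mean["cost"] == pytest.approx(o.expected_cost_per_patient, rel=0.05)


class TestSharedEventRules:
    def test_cohort_rows_reproduce_simulator_flows_exactly(self, params):
        # enumerate catheter days and check the cohort's transition rows
        # against the raw event probabilities the simulator thresholds on
        s = params.strategy("bundle")
        q = params.mortality.crbsi_extra_death
        for d in range(1, params.removal.max_catheter_day + 1):
            fl = cath_day_flows(d, params, s.rr_crbsi)
            row = build_transition_row(f"cath{d}", CycleContext(day=d), s, params)
            assert row["dead"] == pytest.approx(fl["death"] + fl["infection"] * q, abs=1e-15)
            assert row.get(f"crbsi{d + 1}", 0.0) == pytest.approx(fl["to_crbsi"] * (1 - q), abs=1e-15)
            assert row.get("icu1", 0.0) == pytest.approx(
                fl["removal_uninfected"] + fl["removal_infected"] * (1 - q), abs=1e-15)


class TestRegistry:
    def test_mean_age_near_cohort_mean(self, registry):
        se = registry["age"].std() / np.sqrt(len(registry))
        assert abs(registry["age"].mean() - 62.7) < 3 * se

    def test_empirical_band_hazards_match_generator(self, params, registry):
        fit = estimate_parameters(registry)
        for (lo, hi, est, events, at_risk), (_, _, truth) in zip(
                fit.band_hazards, params.infection.day_bands):
            se = np.sqrt(truth * (1 - truth) / at_risk)
            assert abs(est - truth) < 3 * se, (lo, hi)

    def test_schema_and_consistency(self, registry):
        assert registry["patient_id"].is_unique
        inf = registry[registry["infected"] == 1]
        assert (inf["infection_day"] <= inf["catheter_days"] + 1).all()
        assert (registry["catheter_days"] >= 1).all()
        assert (registry[["icu_days", "ward_days"]] >= 0).all().all()
        assert set(registry["end_reason"]) <= {"removed", "infected", "died"}


class TestEstimation:
    def test_small_registry_rejected(self, params):
        reg = generate_registry(200, 1, params, params.strategy("current_practice"))
        with pytest.raises(ValueError, match="1000"):
            estimate_parameters(reg)

    def test_zero_infection_registry_flags_all_bands(self, params):
        reg = generate_registry(2000, 1, params, Strategy("none", 1e-12))
        fit = estimate_parameters(reg)
        assert all(est == 0.0 for _, _, est, _, _ in fit.band_hazards)
        assert len(fit.flagged_bands) == 3

    def test_pipeline_closure_reproduces_infection_risk(self, params, registry):
        # generate -> estimate -> rebuild -> cohort: the fitted model's
        # cumulative infection risk matches the generator within MC error
        fit = estimate_parameters(registry)
        fitted = dataclasses.replace(
            params,
            infection=dataclasses.replace(
                params.infection,
                day_bands=tuple((lo, hi, est) for lo, hi, est, _, _ in fit.band_hazards)),
            removal=dataclasses.replace(
                params.removal, shape=fit.weibull_shape, scale=fit.weibull_scale),
        )
        fitted = calibrate(fitted, infection=False)  # keep the fitted hazards
        cuminf = run_cohort(fitted, Strategy("x", 1.0)).cumulative_infection
        n_inf = registry["infected"].sum()
        mc_se = np.sqrt(n_inf) / len(registry)
        assert abs(cuminf - 0.025) < 4 * mc_se
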