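"""Discrete-time Markov cohort engine.

Catheterised ICU patients are propagated through tunnel states
(catheter-day 1..30), a day-indexed infected track for CR-BSI episodes
(same dwell clock, catheter removed, no reinfection), a post-dwell ICU
tail, the general ward, fifteen post-discharge years and an age-banded
long-term state, to death or an age cap of 100.

Cycles are daily while any cohort mass remains in hospital and annual
thereafter.  Three unpublished inputs — the Weibull removal scale and
the daily ICU and ward death hazards — are recovered by
:func:`calibrate`, which bisects them against the published cumulative
constraints: 2.5% baseline infection risk, 9.8% ICU mortality and 16.1%
hospital mortality.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from . import events
from .parameters import ModelParameters, Strategy

__all__ = [
    "CycleContext",
    "CohortTrace",
    "build_transition_row",
    "run_cohort",
    "calibrate",
    "CalibrationError",
    "UncalibratedError",
]

_MASS_EPS = 1e-15


class UncalibratedError(RuntimeError):
    """The removal scale / death hazards have not been calibrated."""


class CalibrationError(RuntimeError):
    """A calibration target is unreachable within the search bracket."""


@dataclass(frozen=True)
class CycleContext:
    """Calendar context a transition row may depend on."""

    day: int | None = None   # in-hospital day index (1-based)
    year: int | None = None  # post-discharge year index (1-based)
    age: float | None = None  # cohort age at cycle start


def _check_calibrated(p: ModelParameters) -> None:
    if not p.is_calibrated:
        raise UncalibratedError(
            "model parameters are uncalibrated: run crbsi_cea.cohort.calibrate() first "
            "(removal scale and daily death hazards are derived, not configured)"
        )


def _post_removal_state(p: ModelParameters) -> str:
    if p.icu_tail_days > 0:
        return "icu1"
    if p.ward_los_days > 0:
        return "ward1"
    return "discharged"


def build_transition_row(
    state: str, ctx: CycleContext, strategy: Strategy, p: ModelParameters
) -> dict[str, float]:
    """One row of the (time-varying) transition matrix.

    States: ``cath{d}`` catheter tunnel states; ``crbsi{d}`` infected
    ICU tunnel states (catheter removed at infection, dwell clock and
    baseline hazards unchanged, no further infection risk); ``icu{j}``
    post-dwell ICU tail; ``ward{w}``; ``post{y}`` post-discharge years;
    ``longterm``; ``discharged`` (transient pool); absorbing ``dead``.

    The infection-attributable mortality increase (rr_death - 1) x
    hospital cumulative risk is applied at entry to the infected track,
    so a CR-BSI changes survival only by that published absolute
    amount, never by altering exposure time to the calibrated daily
    hazards.  Probabilities in each row sum to 1.
    """
    if state == "dead":
        return {"dead": 1.0}
    _check_calibrated(p)

    if state.startswith("cath"):
        d = int(state[4:])
        fl = events.cath_day_flows(d, p, strategy.rr_crbsi)
        q = p.mortality.crbsi_extra_death
        row = {
            "dead": fl["death"] + (fl["to_crbsi"] + fl["removal_infected"]) * q,
            f"crbsi{d + 1}": fl["to_crbsi"] * (1.0 - q),
            _post_removal_state(p): fl["removal_uninfected"] + fl["removal_infected"] * (1.0 - q),
        }
        if fl["stay"] > 0:
            row[f"cath{d + 1}"] = fl["stay"]
        return {k: v for k, v in row.items() if v != 0.0 or k == "dead"}

    if state.startswith("crbsi"):
        d = int(state[5:])
        eff = events.crbsi_day_events(d, p)
        row = {"dead": eff["death"], _post_removal_state(p): eff["removal"]}
        if eff["stay"] > 0:
            row[f"crbsi{d + 1}"] = eff["stay"]
        return row

    if state.startswith("icu"):
        j = int(state[3:])
        h = p.icu_daily_death
        nxt = f"icu{j + 1}" if j < p.icu_tail_days else ("ward1" if p.ward_los_days > 0 else "discharged")
        return {"dead": h, nxt: 1.0 - h}

    if state.startswith("ward"):
        w = int(state[4:])
        h = p.ward_daily_death
        nxt = f"ward{w + 1}" if w < p.ward_los_days else "discharged"
        return {"dead": h, nxt: 1.0 - h}

    if state.startswith("post"):
        y = int(state[4:])
        h = events.annual_postdischarge_death(y, ctx.age, p)
        last = p.mortality.post_discharge_annual[-1][1]
        nxt = f"post{y + 1}" if y < last else "longterm"
        return {"dead": h, nxt: 1.0 - h}

    if state == "longterm":
        h = 1.0 if ctx.age >= p.age_cap else p.mortality.background(ctx.age)
        return {"dead": h, "longterm": 1.0 - h}

    raise KeyError(f"unknown health state {state!r}")


@dataclass
class CohortTrace:
    """Per-cycle occupancy and event tallies for one strategy.

    ``occupancy``: cycle x state cohort fractions (rows sum to 1).
    ``daily`` / ``annual``: event tallies with mid-cycle times in years.
    Scalar summaries cover the in-hospital phase.
    """

    occupancy: pd.DataFrame
    daily: pd.DataFrame
    annual: pd.DataFrame
    cumulative_infection: float
    surviving_infection: float
    icu_deaths: float
    inhospital_deaths: float
    discharged_alive: float
    mean_discharge_years: float

    def occupancy_long(self) -> pd.DataFrame:
        """Tidy (cycle, elapsed_years, state, occupancy) table for export."""
        long = self.occupancy.stack().rename("occupancy").reset_index()
        long.columns = ["cycle", "state", "occupancy"]
        t = pd.concat([self.daily.set_index("cycle")["t_mid"],
                       self.annual.set_index("cycle")["t_mid"]])
        long["elapsed_years"] = long["cycle"].map(t)
        return long[long["occupancy"] > 0].reset_index(drop=True)


def run_cohort(p: ModelParameters, strategy: Strategy, *, stop_at_discharge: bool = False) -> CohortTrace:
    """Propagate a unit cohort through the model; deterministic.

    Daily cycles run until no mass remains in hospital, annual cycles
    until the age cap.  Post-discharge mass is pooled at its
    mass-weighted mean discharge time (spread is under six weeks, so
    the pooled discount clock is accurate to O(1e-7) QALYs).
    """
    _check_calibrated(p)
    base_age = p.scale.cohort_age

    occ: dict[str, float] = {"cath1": 1.0}
    dead = 0.0
    discharged = 0.0
    t_disch_weighted = 0.0
    cum_inf = 0.0
    surv_inf = 0.0
    icu_deaths = 0.0
    ward_deaths = 0.0

    snapshots: list[dict[str, float]] = []
    daily_rows: list[dict] = []
    cycle = 0
    max_days = p.removal.max_catheter_day + 1 + p.icu_tail_days + p.ward_los_days + 2

    day = 1
    while occ:
        cycle += 1
        if day > max_days:
            raise RuntimeError(f"cohort failed to leave hospital by day {day}")
        if not stop_at_discharge:
            snap = dict(occ)
            snap["dead"] = dead
            snap["discharged"] = discharged
            snapshots.append(snap)

        icu_occ = sum(m for s, m in occ.items() if s.startswith(("cath", "icu", "crbsi")))
        ward_occ = sum(m for s, m in occ.items() if s.startswith("ward"))
        q_extra = p.mortality.crbsi_extra_death

        nxt: dict[str, float] = {}
        d_icu = d_ward = 0.0
        inf_flow = 0.0
        ctx = CycleContext(day=day)
        for state, m in occ.items():
            if m <= _MASS_EPS:
                continue
            if state.startswith("cath"):
                inf_flow += m * events.cath_day_flows(int(state[4:]), p, strategy.rr_crbsi)["infection"]
            row = build_transition_row(state, ctx, strategy, p)
            pdead = row.get("dead", 0.0)
            if state.startswith("ward"):
                d_ward += m * pdead
            else:
                d_icu += m * pdead
            for to, pr in row.items():
                if to == "dead":
                    dead += m * pr
                elif to == "discharged":
                    discharged += m * pr
                    t_disch_weighted += m * pr * day / 365.25
                else:
                    nxt[to] = nxt.get(to, 0.0) + m * pr

        cum_inf += inf_flow
        surv_inf += inf_flow * (1.0 - q_extra)
        icu_deaths += d_icu
        ward_deaths += d_ward
        if stop_at_discharge:
            occ = {s: m for s, m in nxt.items() if m > _MASS_EPS}
            day += 1
            continue
        daily_rows.append({
            "cycle": cycle,
            "day": day,
            "t_mid": (day - 0.5) / 365.25,
            "icu_days": icu_occ,
            "ward_days": ward_occ,
            "new_infections": inf_flow,
            "surviving_infections": inf_flow * (1.0 - q_extra),
            "deaths": d_icu + d_ward,
        })
        occ = {s: m for s, m in nxt.items() if m > _MASS_EPS}
        day += 1
        if any(m != m for m in occ.values()):
            raise RuntimeError(f"NaN occupancy at cycle {cycle}")

    t0 = t_disch_weighted / discharged if discharged > 0 else 0.0

    annual_rows: list[dict] = []
    if not stop_at_discharge:
        alive = discharged
        last_band_year = p.mortality.post_discharge_annual[-1][1]
        y = 1
        while alive > _MASS_EPS:
            age_start = base_age + t0 + (y - 1)
            cycle += 1
            state = f"post{y}" if y <= last_band_year else "longterm"
            if age_start >= p.age_cap:
                # hard cap: remaining mass dies at the year boundary, no accrual
                dead += alive
                snapshots.append({"dead": dead})
                alive = 0.0
                break
            h = events.annual_postdischarge_death(y, age_start, p)
            alive_end = alive * (1.0 - h)
            snapshots.append({state: alive, "dead": dead})
            dead += alive - alive_end
            annual_rows.append({
                "cycle": cycle,
                "year": y,
                "t_start": t0 + (y - 1),
                "t_mid": t0 + y - 0.5,
                "age_mid": age_start + 0.5,
                "alive_start": alive,
                "alive_end": alive_end,
                "deaths": alive - alive_end,
            })
            alive = alive_end
            y += 1

    occupancy = pd.DataFrame(snapshots).fillna(0.0)
    occupancy.index = pd.RangeIndex(1, len(snapshots) + 1, name="cycle")
    daily = pd.DataFrame(daily_rows)
    annual = pd.DataFrame(
        annual_rows,
        columns=["cycle", "year", "t_start", "t_mid", "age_mid", "alive_start", "alive_end", "deaths"],
    )
    return CohortTrace(
        occupancy=occupancy,
        daily=daily,
        annual=annual,
        cumulative_infection=cum_inf,
        surviving_infection=surv_inf,
        icu_deaths=icu_deaths,
        inhospital_deaths=icu_deaths + ward_deaths,
        discharged_alive=discharged,
        mean_discharge_years=t0,
    )


# ---------------------------------------------------------------------------
# calibration

def _baseline(p: ModelParameters) -> Strategy:
    return Strategy("baseline_calibration", 1.0, 0.0)


def _inhospital_stats(p: ModelParameters) -> tuple[float, float, float]:
    tr = run_cohort(p, _baseline(p), stop_at_discharge=True)
    return tr.cumulative_infection, tr.icu_deaths, tr.inhospital_deaths


def _bisect(f, lo, hi, what: str) -> float:
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise CalibrationError(
            f"{what}: target unreachable within bracket [{lo}, {hi}] "
            f"(residuals {flo:.3e}, {fhi:.3e})"
        )
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def calibrate(
    p: ModelParameters,
    *,
    infection: bool = True,
    mortality: bool = True,
    tol: float = 1e-6,
    max_outer: int = 50,
) -> ModelParameters:
    """Solve the unpublished hazards against the published cumulative targets.

    Bisection on (a) the Weibull removal scale so baseline cumulative
    CR-BSI risk equals ``baseline_crbsi_target``, and (b) the daily ICU
    and ward death hazards so baseline cumulative mortality equals
    ``icu_cumulative`` and ``hospital_cumulative``.  The three targets
    interact weakly (deaths censor infection risk and vice versa), so
    the bisections are repeated to a joint fixed point.  Idempotent:
    recalibrating a calibrated model reproduces it.

    Returns a new :class:`ModelParameters`; the input is not modified.
    """
    if infection and not (0.0 < p.baseline_crbsi_target < 1.0):
        raise CalibrationError(
            f"baseline_crbsi_target={p.baseline_crbsi_target} is degenerate; need a value in (0,1)"
        )
    cur = p
    if cur.icu_daily_death is None:
        cur = dataclasses.replace(cur, icu_daily_death=0.01)
    if cur.ward_daily_death is None:
        cur = dataclasses.replace(cur, ward_daily_death=0.01)

    m = cur.mortality
    for _ in range(max_outer):
        if infection:
            def f_scale(scale, base=cur):
                q = dataclasses.replace(base, removal=dataclasses.replace(base.removal, scale=scale))
                return _inhospital_stats(q)[0] - base.baseline_crbsi_target

            scale = _bisect(f_scale, 0.05, 2000.0, "removal scale vs baseline infection risk")
            cur = dataclasses.replace(cur, removal=dataclasses.replace(cur.removal, scale=scale))

        if mortality:
            def f_icu(h, base=cur):
                q = dataclasses.replace(base, icu_daily_death=h)
                return _inhospital_stats(q)[1] - m.icu_cumulative

            h_icu = _bisect(f_icu, 0.0, 0.5, "ICU daily death hazard vs cumulative ICU mortality")
            cur = dataclasses.replace(cur, icu_daily_death=h_icu)

            def f_ward(h, base=cur):
                q = dataclasses.replace(base, ward_daily_death=h)
                return _inhospital_stats(q)[2] - m.hospital_cumulative

            h_ward = _bisect(f_ward, 0.0, 0.9, "ward daily death hazard vs cumulative hospital mortality")
            cur = dataclasses.replace(cur, ward_daily_death=h_ward)

        inf_c, icu_c, hosp_c = _inhospital_stats(cur)
        ok = True
        if infection:
            ok &= abs(inf_c - cur.baseline_crbsi_target) < tol
        if mortality:
            ok &= abs(icu_c - m.icu_cumulative) < tol and abs(hosp_c - m.hospital_cumulative) < tol
        if ok:
            return cur
    raise CalibrationError(f"calibration did not converge in {max_outer} outer iterations")
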