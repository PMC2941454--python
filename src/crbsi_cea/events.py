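"""Per-cycle event rules shared by the cohort engine and the microsimulation.

Both engines draw their daily and annual event probabilities from the
functions here, so they cannot drift apart: the cohort engine combines
them into transition rows, the microsimulation realises them as
sequential Bernoulli draws in the configured event order.

Within an in-hospital day, death is checked first; among survivors,
CR-BSI onset and the end of the ICU dwell (catheter removal) are
conditionally independent Bernoulli events.  Infection is a *marker*:
it triggers the episode's consequences (attributable mortality, costs,
excess bed-days) but never alters the dwell clock, so an infected
patient faces exactly the same exposure to the calibrated daily death
hazards as an uninfected one — the infection's whole survival effect is
the published attributable increase.
"""

from __future__ import annotations

import math

from .parameters import InfectionHazard, ModelParameters, RemovalModel

__all__ = [
    "daily_infection_probability",
    "daily_removal_probability",
    "cath_day_flows",
    "crbsi_day_events",
    "annual_postdischarge_death",
]


def daily_infection_probability(day: int, infection: InfectionHazard, rr: float) -> float:
    """Daily CR-BSI probability on catheter-day ``day`` under hazard ratio ``rr``.

    Band probability times ``rr``, capped at 1; days past the last band
    reuse the last band's value.
    """
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    return min(infection.daily(day) * rr, 1.0)


def _weibull_survival(t: float, shape: float, scale: float) -> float:
    if t <= 0:
        return 1.0
    return math.exp(-((t / scale) ** shape))


def daily_removal_probability(day: int, removal: RemovalModel) -> float:
    """Discrete conditional hazard of Weibull catheter removal on ``day``.

    [S(day-1) - S(day)] / S(day-1) with S(t) = exp(-(t/scale)^shape);
    forced to 1 at ``max_catheter_day``.
    """
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    if day >= removal.max_catheter_day:
        return 1.0
    s0 = _weibull_survival(day - 1, removal.shape, removal.scale)
    s1 = _weibull_survival(day, removal.shape, removal.scale)
    return (s0 - s1) / s0


def cath_day_flows(day: int, p: ModelParameters, rr: float) -> dict[str, float]:
    """Per-day event flows for a catheterised ICU day.

    Death first (probability ``h``); among survivors, infection onset
    (probability ``pi``, the marker) and dwell end / catheter removal
    (probability ``pr``) occur independently.  Keys:

    ``death``              h
    ``infection``          (1-h)·pi — total new infections (the marker tally)
    ``removal_uninfected`` (1-h)·(1-pi)·pr
    ``removal_infected``   (1-h)·pi·pr — infected whose dwell ends the same day
    ``to_crbsi``           (1-h)·pi·(1-pr) — infected continuing the ICU dwell
    ``stay``               (1-h)·(1-pi)·(1-pr)

    The four transition flows plus ``death`` sum to 1 exactly.
    """
    h = p.icu_daily_death
    pi = daily_infection_probability(day, p.infection, rr)
    pr = daily_removal_probability(day, p.removal)
    s = 1.0 - h
    return {
        "death": h,
        "infection": s * pi,
        "removal_uninfected": s * (1.0 - pi) * pr,
        "removal_infected": s * pi * pr,
        "to_crbsi": s * pi * (1.0 - pr),
        "stay": s * (1.0 - pi) * (1.0 - pr),
    }


def crbsi_day_events(day: int, p: ModelParameters) -> dict[str, float]:
    """Per-day event flows for the infected (catheter removed) ICU track.

    Same dwell clock and hazards as the catheterised track, minus the
    infection risk: death first, then the day-indexed dwell-end hazard.
    ``death`` + ``removal`` + ``stay`` sum to 1 exactly.
    """
    h = p.icu_daily_death
    pr = daily_removal_probability(day, p.removal)
    return {"death": h, "removal": (1.0 - h) * pr, "stay": (1.0 - h) * (1.0 - pr)}


def annual_postdischarge_death(year: int, age_at_year_start: float, p: ModelParameters) -> float:
    """Annual death probability ``year`` years after hospital discharge.

    Years 1-15 use the post-ICU follow-up table; later years fall back
    to age-banded population rates.  At or beyond the age cap the whole
    remaining cohort dies (hard cap).
    """
    if age_at_year_start >= p.age_cap:
        return 1.0
    if year <= p.mortality.post_discharge_annual[-1][1]:
        return p.mortality.annual_postdischarge(year)
    return p.mortality.background(age_at_year_start)
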