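"""Patient-level Monte-Carlo oracle and synthetic-registry generator.

Individual trajectories are sampled through the identical event rules
as the cohort engine (both draw probabilities from
:mod:`crbsi_cea.events`), giving a brute-force check on the cohort
expectations and a generator for synthetic registries emulating the
quasi-experimental catheter datasets the model's hazards come from.

Randomness uses one Philox counter-based substream per patient (the
patient index is placed in the counter), so results for patient ``i``
do not depend on ``n`` and every patient consumes a fixed block of
uniforms.  Cohort summaries are computed streaming over fixed-size
chunks, so memory does not grow with ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import events
from .cohort import _check_calibrated
from .parameters import ModelParameters, Perspective, Strategy

__all__ = [
    "PatientPath",
    "SimulationSummary",
    "FittedParameters",
    "simulate_patient",
    "simulate_cohort",
    "generate_registry",
    "estimate_parameters",
]

_AGE_SD = 17.2
_AGE_LO, _AGE_HI = 18.0, 100.0

_METRICS = ("infection", "death_icu", "death_ward", "death_post",
            "icu_days", "ward_days", "cost", "qalys")


# ---------------------------------------------------------------------------
# draw layout: slot 0 = age; 4 uniforms per in-hospital day
# (death, infection, dwell end, attributable death); 1 per post-discharge year

def _draws_per_patient(p: ModelParameters) -> tuple[int, int, int]:
    max_days = p.removal.max_catheter_day + 1 + p.icu_tail_days + p.ward_los_days
    max_years = int(np.ceil(p.age_cap - _AGE_LO)) + 1
    return 1 + 4 * max_days + max_years, max_days, max_years


def _patient_rng(seed: int, pid: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, pid, 0]))


def _band_lookup(bands, x: np.ndarray) -> np.ndarray:
    """Vectorised nearest-band value lookup (same rule as the scalar one)."""
    conds = [(x >= lo) & (x <= hi) for lo, hi, _ in bands]
    vals = [v for _, _, v in bands]
    below = x < bands[0][0]
    return np.select([below] + conds, [bands[0][2]] + vals, default=bands[-1][2])


def _run_paths(U: np.ndarray, ages: np.ndarray, p: ModelParameters, s: Strategy,
               persp: Perspective) -> dict[str, np.ndarray]:
    """Vectorised realisation of the shared event rules for a block of patients."""
    _check_calibrated(p)
    n, _ = U.shape
    c, u = p.costs, p.utilities
    rate = persp.discount_rate
    icu_rate, ward_rate = persp.icu_rate(c), persp.ward_rate(c)
    fixed_episode = c.diagnostics + c.treatment
    excess = c.excess_icu_days * icu_rate + c.excess_ward_days * ward_rate
    q_extra = p.mortality.crbsi_extra_death
    h_icu, h_ward = p.icu_daily_death, p.ward_daily_death
    tail, wlos = p.icu_tail_days, p.ward_los_days
    _, max_days, max_years = _draws_per_patient(p)

    pi = np.array([events.daily_infection_probability(d, p.infection, s.rr_crbsi)
                   for d in range(1, max_days + 1)])
    pr = np.array([events.daily_removal_probability(d, p.removal)
                   for d in range(1, max_days + 1)])

    # stages: 0 catheterised, 1 infected ICU track, 2 ICU tail, 3 ward,
    #         4 discharged, 5 dead
    stage = np.zeros(n, dtype=np.int8)
    icu_exit = np.full(n, -1)
    ward_exit = np.full(n, -1)
    infected = np.zeros(n, dtype=bool)
    episode_survivor = np.zeros(n, dtype=bool)
    infection_day = np.full(n, -1)
    cath_end_day = np.zeros(n, dtype=np.int64)
    end_reason = np.zeros(n, dtype=np.int8)  # 0 removed, 1 infected, 2 died
    death_phase = np.zeros(n, dtype=np.int8)  # 0 none, 1 icu, 2 ward, 3 post
    death_year = np.full(n, -1)
    discharge_day = np.zeros(n, dtype=np.int64)
    icu_days = np.zeros(n)
    ward_days = np.zeros(n)
    cost = np.full(n, float(s.per_catheter_cost))
    qalys = np.zeros(n)

    def _exit_dwell(mask: np.ndarray, g: int) -> None:
        """Route patients whose ICU dwell ends on day g into tail/ward."""
        if tail > 0:
            stage[mask] = 2
            icu_exit[mask] = g + tail
        elif wlos > 0:
            stage[mask] = 3
            ward_exit[mask] = g + wlos
        else:
            stage[mask] = 4
            discharge_day[mask] = g

    for g in range(1, max_days + 1):
        active = stage <= 3
        if not active.any():
            break
        ug = U[:, 1 + 4 * (g - 1): 1 + 4 * g]
        in_icu = active & (stage <= 2)
        in_ward = active & (stage == 3)
        icu_days += in_icu
        ward_days += in_ward
        df = (1.0 + rate) ** (-(g - 0.5) / 365.25)
        cost += df * (in_icu * icu_rate + in_ward * ward_rate)
        qalys += df * (in_icu * u.icu_and_early_postdischarge + in_ward * u.ward) / 365.25

        die = active & (ug[:, 0] < np.where(stage == 3, h_ward, h_icu))
        death_phase[die] = np.where(in_ward[die], 2, 1)
        died_cath = die & (stage == 0)
        cath_end_day[died_cath] = g
        end_reason[died_cath] = 2
        stage[die] = 5

        surv = active & ~die
        # infection marker among catheterised death-survivors
        inf = surv & (stage == 0) & (ug[:, 1] < pi[g - 1])
        infected[inf] = True
        infection_day[inf] = g
        cath_end_day[inf] = g
        end_reason[inf] = 1
        cost[inf] += df * fixed_episode
        inf_die = inf & (ug[:, 3] < q_extra)
        episode_survivor |= inf & ~inf_die
        cost[inf & ~inf_die] += df * excess
        death_phase[inf_die] = 1
        stage[inf_die] = 5

        # dwell end, independent of infection, for catheter and infected tracks
        dwell = (stage <= 1) & ~(stage == 5) & surv & ~inf_die
        rem = dwell & (ug[:, 2] < pr[g - 1])
        removed_cath = rem & (stage == 0) & ~inf
        cath_end_day[removed_cath] = g
        # infected patients who continue the dwell move to the infected track
        cont_inf = inf & ~inf_die & ~rem
        stage[cont_inf] = 1
        _exit_dwell(rem, g)

        # scheduled exits from the fixed-length tail and ward stays
        tail_done = (stage == 2) & surv & (icu_exit == g)
        if wlos > 0:
            stage[tail_done] = 3
            ward_exit[tail_done] = g + wlos
        else:
            stage[tail_done] = 4
            discharge_day[tail_done] = g
        ward_done = (stage == 3) & surv & (ward_exit == g)
        stage[ward_done] = 4
        discharge_day[ward_done] = g

    # annual post-discharge phase on each patient's own clock
    t0 = discharge_day / 365.25
    pd_alive = stage == 4
    last_band_year = p.mortality.post_discharge_annual[-1][1]
    base_annual = 1 + 4 * max_days
    for y in range(1, max_years + 1):
        if not pd_alive.any():
            break
        age_start = ages + t0 + (y - 1)
        capped = pd_alive & (age_start >= p.age_cap)
        death_phase[capped] = 3
        death_year[capped] = y
        stage[capped] = 5
        pd_alive &= ~capped
        if not pd_alive.any():
            break
        if y <= last_band_year:
            h = np.full(n, p.mortality.annual_postdischarge(y))
        else:
            h = _band_lookup(p.mortality.background_annual_by_age, age_start)
        uy = U[:, base_annual + (y - 1)]
        die_y = pd_alive & (uy < h)
        age_mid = ages + t0 + y - 0.5
        norm = _band_lookup(u.population_norms_by_age, age_mid)
        util = 0.5 * (u.icu_and_early_postdischarge + norm) if y == 1 else norm
        df = (1.0 + rate) ** (-(t0 + y - 0.5))
        qalys += df * util * (pd_alive & ~die_y)
        if p.half_cycle_correction:
            qalys += 0.5 * df * util * die_y
        death_phase[die_y] = 3
        death_year[die_y] = y
        stage[die_y] = 5
        pd_alive &= ~die_y

    return {
        "age": ages,
        "infected": infected,
        "episode_survivor": episode_survivor,
        "infection_day": infection_day,
        "catheter_days": cath_end_day,
        "end_reason": end_reason,
        "death_phase": death_phase,
        "death_year": death_year,
        "icu_days": icu_days,
        "ward_days": ward_days,
        "discharge_day": discharge_day,
        "cost": cost,
        "qalys": qalys,
    }


@dataclass(frozen=True)
class PatientPath:
    """One sampled trajectory."""

    patient_id: int
    age: float
    catheter_days: int
    infected: bool
    infection_day: int | None
    died: bool
    death_phase: str | None  # "icu" | "ward" | "post_discharge"
    death_year: int | None
    icu_days: float
    ward_days: float
    discounted_cost: float
    discounted_qalys: float


_PHASES = {0: None, 1: "icu", 2: "ward", 3: "post_discharge"}
_REASONS = {0: "removed", 1: "infected", 2: "died"}


def _path_from_arrays(res: dict[str, np.ndarray], i: int, pid: int,
                      p: ModelParameters) -> PatientPath:
    phase = _PHASES[int(res["death_phase"][i])]
    inf = bool(res["infected"][i])
    # the deterministic excess bed-days attach to episode survivors only
    surv = bool(res["episode_survivor"][i])
    extra_icu = p.costs.excess_icu_days if surv else 0.0
    extra_ward = p.costs.excess_ward_days if surv else 0.0
    return PatientPath(
        patient_id=pid,
        age=float(res["age"][i]),
        catheter_days=int(res["catheter_days"][i]),
        infected=inf,
        infection_day=int(res["infection_day"][i]) if inf else None,
        died=phase is not None,
        death_phase=phase,
        death_year=int(res["death_year"][i]) if res["death_year"][i] > 0 else None,
        icu_days=float(res["icu_days"][i]) + extra_icu,
        ward_days=float(res["ward_days"][i]) + extra_ward,
        discounted_cost=float(res["cost"][i]),
        discounted_qalys=float(res["qalys"][i]),
    )


def simulate_patient(rng: np.random.Generator, p: ModelParameters, s: Strategy,
                     persp: Perspective, *, age: float | None = None,
                     patient_id: int = 0) -> PatientPath:
    """Sample a single trajectory from ``rng``; deterministic given its state."""
    K, _, _ = _draws_per_patient(p)
    U = rng.random((1, K))
    a = p.scale.cohort_age if age is None else age
    res = _run_paths(U, np.array([a]), p, s, persp)
    return _path_from_arrays(res, 0, patient_id, p)


@dataclass(frozen=True)
class SimulationSummary:
    """Streaming means and Monte-Carlo standard errors over ``n`` patients."""

    n: int
    seed: int
    mean: dict[str, float]
    se: dict[str, float]

    def to_json_dict(self) -> dict:
        return {"n": self.n, "seed": self.seed, "mean": self.mean, "se": self.se}


def _block_uniforms(seed: int, pids: np.ndarray, K: int) -> np.ndarray:
    out = np.empty((len(pids), K))
    for row, pid in enumerate(pids):
        out[row] = _patient_rng(seed, int(pid)).random(K)
    return out


def _truncnorm_loc(target_mean: float) -> float:
    """Location parameter giving the truncated normal the target mean.

    Truncation to [18, 100] is asymmetric around the cohort mean, so
    the location is shifted (solved once) to keep the sampled mean age
    at the published value.
    """
    def gap(loc):
        a, b = (_AGE_LO - loc) / _AGE_SD, (_AGE_HI - loc) / _AGE_SD
        return stats.truncnorm.mean(a, b, loc=loc, scale=_AGE_SD) - target_mean

    return optimize.brentq(gap, _AGE_LO, _AGE_HI, xtol=1e-10)


def _sample_ages(U0: np.ndarray, mean: float) -> np.ndarray:
    loc = _truncnorm_loc(mean)
    a = (_AGE_LO - loc) / _AGE_SD
    b = (_AGE_HI - loc) / _AGE_SD
    return stats.truncnorm.ppf(U0, a, b, loc=loc, scale=_AGE_SD)


def simulate_cohort(n: int, seed: int, p: ModelParameters, s: Strategy,
                    persp: Perspective, *, sample_ages: bool = False,
                    chunk: int = 20000) -> SimulationSummary:
    """Monte-Carlo summary over ``n`` patients; memory independent of ``n``.

    With ``sample_ages=False`` (default) every patient carries the
    cohort mean age, matching the cohort engine's assumption; with
    ``sample_ages=True`` ages are drawn from the registry distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    K, _, _ = _draws_per_patient(p)
    sums = {k: 0.0 for k in _METRICS}
    sumsq = {k: 0.0 for k in _METRICS}
    for start in range(0, n, chunk):
        pids = np.arange(start, min(start + chunk, n))
        U = _block_uniforms(seed, pids, K)
        ages = _sample_ages(U[:, 0], p.scale.cohort_age) if sample_ages \
            else np.full(len(pids), p.scale.cohort_age)
        res = _run_paths(U, ages, p, s, persp)
        surv = res["episode_survivor"].astype(float)
        vals = {
            "infection": res["infected"].astype(float),
            "death_icu": (res["death_phase"] == 1).astype(float),
            "death_ward": (res["death_phase"] == 2).astype(float),
            "death_post": (res["death_phase"] == 3).astype(float),
            "icu_days": res["icu_days"] + p.costs.excess_icu_days * surv,
            "ward_days": res["ward_days"] + p.costs.excess_ward_days * surv,
            "cost": res["cost"],
            "qalys": res["qalys"],
        }
        for k, v in vals.items():
            sums[k] += float(v.sum())
            sumsq[k] += float((v ** 2).sum())
    mean = {k: sums[k] / n for k in _METRICS}
    se = {}
    for k in _METRICS:
        var = max(sumsq[k] / n - mean[k] ** 2, 0.0)
        se[k] = float(np.sqrt(var / max(n - 1, 1)))
    return SimulationSummary(n=n, seed=seed, mean=mean, se=se)


# ---------------------------------------------------------------------------
# synthetic registries and re-estimation of the model's hazards

_REGISTRY_COLUMNS = [
    "patient_id", "age", "catheter_days", "end_reason", "infected",
    "infection_day", "death_phase", "death_year", "icu_days", "ward_days",
    "discounted_cost", "discounted_qalys",
]


def generate_registry(n: int, seed: int, p: ModelParameters, s: Strategy,
                      persp: Perspective | None = None, *, path=None,
                      chunk: int = 20000) -> pd.DataFrame:
    """Synthetic per-patient registry emulating the catheter datasets
    behind the model's hazards.

    Ages are drawn from a truncated normal (mean = cohort age, sd 17.2,
    support [18, 100]).  One row per patient; deterministic given
    ``(n, seed)``.  If ``path`` is given the table is also written as
    CSV with a fixed float format, so identical seeds give identical
    bytes.
    """
    from .parameters import PERSPECTIVES

    if n < 1:
        raise ValueError("n must be >= 1")
    persp = persp or PERSPECTIVES["baseline"]
    K, _, _ = _draws_per_patient(p)
    frames = []
    for start in range(0, n, chunk):
        pids = np.arange(start, min(start + chunk, n))
        U = _block_uniforms(seed, pids, K)
        ages = _sample_ages(U[:, 0], p.scale.cohort_age)
        res = _run_paths(U, ages, p, s, persp)
        surv = res["episode_survivor"]
        frames.append(pd.DataFrame({
            "patient_id": pids,
            "age": np.round(res["age"], 4),
            "catheter_days": res["catheter_days"],
            "end_reason": pd.Series(res["end_reason"]).map({0: "removed", 1: "infected", 2: "died"}).values,
            "infected": res["infected"].astype(int),
            "infection_day": res["infection_day"],
            "death_phase": pd.Series(res["death_phase"]).map(_PHASES).fillna("none").values,
            "death_year": res["death_year"],
            "icu_days": res["icu_days"] + p.costs.excess_icu_days * surv,
            "ward_days": res["ward_days"] + p.costs.excess_ward_days * surv,
            "discounted_cost": np.round(res["cost"], 6),
            "discounted_qalys": np.round(res["qalys"], 8),
        }))
    reg = pd.concat(frames, ignore_index=True)[_REGISTRY_COLUMNS]
    reg.loc[reg["death_phase"].isna(), "death_phase"] = "none"
    if path is not None:
        reg.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
    return reg


@dataclass(frozen=True)
class FittedParameters:
    """Hazards re-estimated from a registry.

    ``band_hazards`` holds (first_day, last_day, estimate, events,
    at_risk_days) per infection band; bands with too few events are
    listed in ``flagged_bands``.  The Weibull dwell fit treats
    infections and in-catheter deaths as right-censoring and the forced
    removal at the maximum day as censoring at day max-1.
    """

    band_hazards: tuple[tuple[int, int, float, int, float], ...]
    weibull_shape: float
    weibull_scale: float
    n_catheters: int
    flagged_bands: tuple[tuple[int, int], ...]


def estimate_parameters(registry: pd.DataFrame, *,
                        infection_bands=None,
                        max_catheter_day: int = 30,
                        min_events: int = 5) -> FittedParameters:
    """Re-enact the estimation step on a (synthetic) registry.

    Banded infection hazards are events per at-risk catheter-day; the
    Weibull removal-time fit maximises the interval-censored likelihood
    (removal on day d lies in (d-1, d]).
    """
    if infection_bands is None:
        from .parameters import InfectionHazard
        infection_bands = InfectionHazard().day_bands
    n = len(registry)
    if n < 1000:
        raise ValueError(f"registry too small for estimation: {n} < 1000 catheters")

    end = registry["catheter_days"].to_numpy()
    reason = registry["end_reason"].to_numpy()
    infected = registry["infected"].to_numpy().astype(bool)
    inf_day = registry["infection_day"].to_numpy()

    # days at infection risk: through the end day, except the death day
    # itself (the death check precedes the infection check within a day)
    risk_end = np.where(reason == "died", end - 1, end)

    bands = []
    flagged = []
    for lo, hi, _ in infection_bands:
        at_risk = np.clip(np.minimum(risk_end, hi) - lo + 1, 0, None).sum()
        ev = int((infected & (inf_day >= lo) & (inf_day <= hi)).sum())
        est = ev / at_risk if at_risk > 0 else 0.0
        bands.append((lo, hi, float(est), ev, float(at_risk)))
        if ev < min_events:
            flagged.append((lo, hi))

    # interval-censored Weibull MLE on dwell times
    observed = (reason == "removed") & (end < max_catheter_day)
    cens_day = np.where(reason == "died", end - 1,
                        np.where(reason == "infected", end - 1, end - 1))
    d_obs = end[observed].astype(float)
    c_obs = cens_day[~observed].astype(float)
    c_obs = c_obs[c_obs > 0]

    def nll(x):
        shape, scale = np.exp(x)
        s0 = np.exp(-(((d_obs - 1) / scale) ** shape))
        s1 = np.exp(-((d_obs / scale) ** shape))
        ll = np.log(np.clip(s0 - s1, 1e-300, None)).sum()
        ll += (-((c_obs / scale) ** shape)).sum()
        return -ll

    x0 = np.log([1.0, max(d_obs.mean() if len(d_obs) else 5.0, 1.0)])
    fit = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    shape, scale = np.exp(fit.x)
    return FittedParameters(
        band_hazards=tuple(bands),
        weibull_shape=float(shape),
        weibull_scale=float(scale),
        n_catheters=n,
        flagged_bands=tuple(flagged),
    )
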