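"""Model inputs for the CVC infection-control cost-effectiveness model.

Everything the model consumes lives here: the epidemiology of
catheter-related bloodstream infection (CR-BSI) in Level III Australian
ICUs (daily infection hazards by catheter-day band, catheter removal
model, baseline and infection-attributable mortality), utility weights,
2006-AUD unit costs, the candidate infection-control strategies, and the
nationwide scale assumptions used to turn per-patient results into
program budgets.

Defaults are the published point estimates of the evaluation this
package reproduces.  Validation is data, not exceptions:
:func:`validate_parameters` returns a list of human-readable violations
so configuration errors can be reported in bulk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any

import yaml

SCHEMA_VERSION = 1

__all__ = [
    "InfectionHazard",
    "RemovalModel",
    "MortalityTable",
    "UtilityTable",
    "CostInputs",
    "Strategy",
    "Perspective",
    "ScaleAssumptions",
    "ModelParameters",
    "PERSPECTIVES",
    "default_parameters",
    "validate_parameters",
    "load_config",
    "save_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration file cannot be loaded or is invalid."""


Band = tuple[int, int, float]


def _bands(raw) -> tuple[Band, ...]:
    return tuple((int(a), int(b), float(v)) for a, b, v in raw)


def _band_value(bands: tuple[Band, ...], x: float, *, nearest: bool = True) -> float:
    """Value of the band containing x; outside the table, nearest band."""
    for lo, hi, v in bands:
        if lo <= x <= hi:
            return v
    if not nearest:
        raise KeyError(x)
    if x < bands[0][0]:
        return bands[0][2]
    return bands[-1][2]


@dataclass(frozen=True)
class InfectionHazard:
    """Daily CR-BSI probability, stepwise in catheter-day bands.

    Risk increases with duration of catheterisation: 0.004/day for days
    1-5, 0.009/day for days 6-15, 0.020/day for days 16-30.  Days past
    the last band reuse the last band's value.
    """

    day_bands: tuple[Band, ...] = ((1, 5, 0.004), (6, 15, 0.009), (16, 30, 0.020))

    @property
    def last_day(self) -> int:
        return self.day_bands[-1][1]

    def daily(self, day: int) -> float:
        if day < 1:
            raise ValueError(f"catheter day must be >= 1, got {day}")
        return _band_value(self.day_bands, day)


@dataclass(frozen=True)
class RemovalModel:
    """Weibull time-to-removal for catheters no longer necessary.

    The source study's fitted parameters are unpublished; the shape is a
    structural default and the scale is always recalibrated so the
    baseline cumulative infection risk hits ``baseline_crbsi_target``.
    Removal is forced (probability 1) at ``max_catheter_day``.
    """

    shape: float = 1.5
    scale: float = 7.0
    max_catheter_day: int = 30


@dataclass(frozen=True)
class MortalityTable:
    """Baseline and CR-BSI-attributable mortality.

    ``icu_cumulative``/``hospital_cumulative`` are cumulative risks for
    the catheterised cohort (9.8% in ICU, 16.1% by hospital discharge);
    the daily hazards that reproduce them are calibrated, not stated.
    ``rr_death_crbsi`` is the relative risk of hospital death given
    CR-BSI; it is applied as a one-off absolute increase of
    (rr-1) x hospital_cumulative during the infection episode.
    Post-discharge annual probabilities cover 15 years, after which
    age-banded population rates apply.
    """

    icu_cumulative: float = 0.098
    hospital_cumulative: float = 0.161
    rr_death_crbsi: float = 1.06
    post_discharge_annual: tuple[Band, ...] = (
        (1, 1, 0.050),
        (2, 3, 0.027),
        (4, 5, 0.028),
        (6, 10, 0.037),
        (11, 15, 0.042),
    )
    background_annual_by_age: tuple[Band, ...] = (
        (45, 64, 0.004),
        (65, 84, 0.030),
        (85, 999, 0.140),
    )

    def annual_postdischarge(self, year: int) -> float:
        return _band_value(self.post_discharge_annual, year)

    def background(self, age: float) -> float:
        return _band_value(self.background_annual_by_age, age)

    @property
    def crbsi_extra_death(self) -> float:
        """Absolute in-hospital mortality increase attributable to CR-BSI."""
        return (self.rr_death_crbsi - 1.0) * self.hospital_cumulative


@dataclass(frozen=True)
class UtilityTable:
    """Health-state utility weights.

    0.66 applies to ICU cycles and the first 6 months post-discharge
    (and, by assumption, to ward cycles — unstated in the source, kept
    configurable).  Thereafter age-banded population norms apply; ages
    below the first band take the nearest band's value.
    """

    icu_and_early_postdischarge: float = 0.66
    ward: float = 0.66
    population_norms_by_age: tuple[Band, ...] = (
        (50, 59, 0.80),
        (60, 69, 0.79),
        (70, 79, 0.75),
        (80, 999, 0.66),
    )

    def norm(self, age: float) -> float:
        return _band_value(self.population_norms_by_age, age)


@dataclass(frozen=True)
class CostInputs:
    """Unit costs in 2006 AUD.

    Full bed-day values are short-run average costs; the ``_variable``
    values are the consumable-only alternatives used by the perspective
    sensitivity analyses.  Excess stay attributable to a CR-BSI episode
    is 2.41 ICU + 7.54 ward days.
    """

    icu_bed_day: float = 3021.0
    ward_bed_day: float = 843.0
    icu_bed_day_variable: float = 362.0
    ward_bed_day_variable: float = 101.0
    excess_icu_days: float = 2.41
    excess_ward_days: float = 7.54
    diagnostics: float = 101.7
    treatment: float = 591.3


@dataclass(frozen=True)
class Strategy:
    """An infection-control option.

    ``rr_crbsi`` multiplies the daily infection hazard;
    ``per_catheter_cost`` is the consumable cost incurred at insertion;
    ``program_cost_nationwide`` is an 18-month implementation budget
    (zero for catheters, the solved unknown for the care bundle).
    """

    name: str
    rr_crbsi: float
    per_catheter_cost: float = 0.0
    program_cost_nationwide: float = 0.0


@dataclass(frozen=True)
class Perspective:
    """A decision-maker's valuation of outcomes.

    ``wtp_per_qaly`` is the willingness to pay for a QALY (AUD);
    ``bed_day_valuation`` selects full vs variable bed-day values;
    costs and QALYs are discounted at ``discount_rate`` per year.
    """

    name: str = "baseline"
    wtp_per_qaly: float = 64000.0
    bed_day_valuation: str = "full"  # "full" | "variable"
    discount_rate: float = 0.03

    def icu_rate(self, costs: CostInputs) -> float:
        return costs.icu_bed_day if self.bed_day_valuation == "full" else costs.icu_bed_day_variable

    def ward_rate(self, costs: CostInputs) -> float:
        return costs.ward_bed_day if self.bed_day_valuation == "full" else costs.ward_bed_day_variable


PERSPECTIVES: dict[str, Perspective] = {
    "baseline": Perspective("baseline", 64000.0, "full"),
    "no_qaly": Perspective("no_qaly", 0.0, "full"),
    "variable_beds": Perspective("variable_beds", 64000.0, "variable"),
    "cash_only": Perspective("cash_only", 0.0, "variable"),
}


@dataclass(frozen=True)
class ScaleAssumptions:
    """Nationwide scale: 53,470 annual Level III ICU admissions across 46
    units, 17% catheterised, 18-month program horizon, cohort mean age 62.7."""

    annual_admissions: int = 53470
    catheterised_fraction: float = 0.17
    horizon_years: float = 1.5
    n_icus: int = 46
    cohort_age: float = 62.7


@dataclass(frozen=True)
class ModelParameters:
    """Composite of every model input plus structural switches.

    ``icu_daily_death``/``ward_daily_death`` and the removal scale are
    produced by :func:`crbsi_cea.cohort.calibrate`; until then the
    cohort engine refuses to run.
    """

    infection: InfectionHazard = field(default_factory=InfectionHazard)
    removal: RemovalModel = field(default_factory=RemovalModel)
    mortality: MortalityTable = field(default_factory=MortalityTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    costs: CostInputs = field(default_factory=CostInputs)
    scale: ScaleAssumptions = field(default_factory=ScaleAssumptions)
    strategies: tuple[Strategy, ...] = (
        Strategy("current_practice", 1.0, 0.0),
        Strategy("chssd", 0.66, 11.64),
        Strategy("mr", 0.39, 59.36),
        Strategy("bundle", 0.34, 0.0),
    )
    perspectives: tuple[Perspective, ...] = (
        Perspective("baseline", 64000.0, "full"),
        Perspective("no_qaly", 0.0, "full"),
        Perspective("variable_beds", 64000.0, "variable"),
        Perspective("cash_only", 0.0, "variable"),
    )
    baseline_crbsi_target: float = 0.025
    # structural assumptions (unpublished in the source; see docs/methods.md)
    icu_tail_days: int = 1
    ward_los_days: int = 7
    half_cycle_correction: bool = True
    age_cap: float = 100.0
    # calibrated daily death hazards; None until calibrate() has run
    icu_daily_death: float | None = None
    ward_daily_death: float | None = None

    @property
    def is_calibrated(self) -> bool:
        return self.icu_daily_death is not None and self.ward_daily_death is not None

    def strategy(self, name: str) -> Strategy:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"unknown strategy {name!r}")

    def perspective(self, name: str) -> Perspective:
        for q in self.perspectives:
            if q.name == name:
                return q
        raise KeyError(f"unknown perspective {name!r}")


def default_parameters() -> ModelParameters:
    """The published baseline inputs (uncalibrated)."""
    return ModelParameters()


# ---------------------------------------------------------------------------
# validation

def _prob(x) -> bool:
    return isinstance(x, (int, float)) and 0.0 <= x <= 1.0


def validate_parameters(p: ModelParameters) -> list[str]:
    """Check every invariant; return a list of violations (empty iff valid)."""
    v: list[str] = []

    bands = p.infection.day_bands
    if not bands:
        v.append("infection.day_bands: must be non-empty")
    else:
        if bands[0][0] != 1:
            v.append("infection.day_bands: first band must start at day 1")
        prev_hi, prev_p = None, -1.0
        for lo, hi, prob in bands:
            if lo > hi:
                v.append(f"infection.day_bands: band ({lo},{hi}) has first_day > last_day")
            if prev_hi is not None and lo != prev_hi + 1:
                v.append(f"infection.day_bands: band starting day {lo} not contiguous with previous (overlap or gap)")
            if not (0.0 <= prob < 1.0):
                v.append(f"infection.day_bands: probability {prob} outside [0,1)")
            if prob < prev_p:
                v.append("infection.day_bands: probabilities must be non-decreasing across bands")
            prev_hi, prev_p = hi, prob

    r = p.removal
    if not (r.shape > 0 and r.shape == r.shape and r.shape != float("inf")):
        v.append(f"removal.shape: must be finite positive, got {r.shape}")
    if not (r.scale > 0 and r.scale != float("inf")):
        v.append(f"removal.scale: must be finite positive, got {r.scale}")
    if r.max_catheter_day < 1:
        v.append("removal.max_catheter_day: must be >= 1")

    m = p.mortality
    for name in ("icu_cumulative", "hospital_cumulative"):
        if not _prob(getattr(m, name)):
            v.append(f"mortality.{name}: must be a probability in [0,1]")
    if m.hospital_cumulative < m.icu_cumulative:
        v.append("mortality.hospital_cumulative: must be >= icu_cumulative")
    if m.rr_death_crbsi < 1.0:
        v.append("mortality.rr_death_crbsi: rr >= 1 required")
    for lo, hi, prob in m.post_discharge_annual + m.background_annual_by_age:
        if not _prob(prob):
            v.append(f"mortality: annual probability {prob} for band ({lo},{hi}) outside [0,1]")

    u = p.utilities
    weights = [u.icu_and_early_postdischarge, u.ward] + [w for _, _, w in u.population_norms_by_age]
    for w in weights:
        if not _prob(w):
            v.append(f"utilities: weight {w} outside [0,1]")

    c = p.costs
    for name in ("icu_bed_day", "ward_bed_day", "icu_bed_day_variable",
                 "ward_bed_day_variable", "excess_icu_days", "excess_ward_days",
                 "diagnostics", "treatment"):
        if getattr(c, name) < 0:
            v.append(f"costs.{name}: must be >= 0")
    if c.icu_bed_day_variable > c.icu_bed_day:
        v.append("costs.icu_bed_day_variable: must be <= icu_bed_day")
    if c.ward_bed_day_variable > c.ward_bed_day:
        v.append("costs.ward_bed_day_variable: must be <= ward_bed_day")

    for s in p.strategies:
        if not (0.0 < s.rr_crbsi <= 1.0):
            v.append(f"strategies[{s.name}].rr_crbsi: must be in (0,1], got {s.rr_crbsi}")
        if s.per_catheter_cost < 0 or s.program_cost_nationwide < 0:
            v.append(f"strategies[{s.name}]: costs must be >= 0")

    for q in p.perspectives:
        if q.wtp_per_qaly < 0:
            v.append(f"perspectives[{q.name}].wtp_per_qaly: must be >= 0")
        if not (0.0 <= q.discount_rate < 1.0):
            v.append(f"perspectives[{q.name}].discount_rate: must be in [0,1)")
        if q.bed_day_valuation not in ("full", "variable"):
            v.append(f"perspectives[{q.name}].bed_day_valuation: must be 'full' or 'variable'")

    sc = p.scale
    if sc.annual_admissions < 0:
        v.append("scale.annual_admissions: must be >= 0")
    if not (0.0 < sc.catheterised_fraction <= 1.0):
        v.append("scale.catheterised_fraction: must be in (0,1]")
    if sc.horizon_years <= 0:
        v.append("scale.horizon_years: must be positive")
    if sc.n_icus < 1:
        v.append("scale.n_icus: must be >= 1")
    if not (0 < sc.cohort_age < p.age_cap):
        v.append("scale.cohort_age: must lie in (0, age_cap)")

    if not (0.0 < p.baseline_crbsi_target < 1.0):
        v.append("baseline_crbsi_target: must be in (0,1)")
    if p.icu_tail_days < 0 or p.ward_los_days < 0:
        v.append("icu_tail_days/ward_los_days: must be >= 0")
    if p.mortality.crbsi_extra_death >= 1.0:
        v.append("mortality.rr_death_crbsi: attributable death probability must be < 1")
    if p.icu_daily_death is not None and not _prob(p.icu_daily_death):
        v.append("icu_daily_death: must be a probability in [0,1]")
    if p.ward_daily_death is not None and not _prob(p.ward_daily_death):
        v.append("ward_daily_death: must be a probability in [0,1]")
    return v


# ---------------------------------------------------------------------------
# config file round-trip (YAML, schema_version 1)

def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, list):
        return [_to_plain(x) for x in obj]
    return obj


_SECTIONS = {
    "infection": InfectionHazard,
    "removal": RemovalModel,
    "mortality": MortalityTable,
    "utilities": UtilityTable,
    "costs": CostInputs,
    "scale": ScaleAssumptions,
}

_BAND_FIELDS = {
    "day_bands",
    "post_discharge_annual",
    "background_annual_by_age",
    "population_norms_by_age",
}


def _from_dict(cls, data: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} in {path}")
    kwargs = {}
    for key, val in data.items():
        if key in _BAND_FIELDS:
            kwargs[key] = _bands(val)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def save_config(p: ModelParameters, path) -> None:
    """Write parameters as a human-editable YAML file."""
    doc = {"schema_version": SCHEMA_VERSION}
    doc.update(_to_plain(p))
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> ModelParameters:
    """Load, structurally check and validate a YAML configuration.

    Raises :class:`ConfigError` for unknown fields, bad structure or any
    parameter-invariant violation.
    """
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except yaml.YAMLError as e:
        raise ConfigError(f"unparsable config {path}: {e}") from None
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} must be a mapping")
    doc = dict(doc)
    version = doc.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")

    top_names = {f.name for f in fields(ModelParameters)}
    unknown = set(doc) - top_names
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} at top level")

    kwargs: dict[str, Any] = {}
    for key, val in doc.items():
        if key in _SECTIONS:
            kwargs[key] = _from_dict(_SECTIONS[key], val, key)
        elif key == "strategies":
            kwargs[key] = tuple(_from_dict(Strategy, s, f"strategies[{i}]") for i, s in enumerate(val))
        elif key == "perspectives":
            kwargs[key] = tuple(_from_dict(Perspective, q, f"perspectives[{i}]") for i, q in enumerate(val))
        else:
            kwargs[key] = val
    p = ModelParameters(**kwargs)
    violations = validate_parameters(p)
    if violations:
        raise ConfigError("invalid configuration:\n" + "\n".join(f"  - {x}" for x in violations))
    return p
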