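"""Scenario construction: growth-rate schedules, initial states and introductions.

Five scenarios of parental growth rates are modelled (r in 1/day):

* A — both parental species grow equally fast (r1 = r2 = 0.35);
* B — species 1 grows faster (r1 = 0.35, r2 = 0.30);
* C — the parental rates swap every two years, species 1 starting at the
  lower value;
* D — the parental rates swap within each year at day 166, species 1
  starting at the lower value;
* E — species 1 (r1 = 0.30) holds the lake alone for 100 years, then
  species 2 (r2 = 0.35) is introduced at the colonization density and the
  run continues another 100 years.

Throughout, backcross rates are the instantaneous mean of the respective
parental rate and the F1 rate, F2-hybrids grow at 0.30 (hybrid breakdown),
and the F1 rate r3 is a free input (default 0.35).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model_core import (
    N_CLASSES,
    YEAR_LENGTH,
    CommunityState,
    HybridClass,
    ModelParameters,
    SeasonCalendar,
    day_of_year,
)

__all__ = [
    "ClassRule",
    "ConstantRule",
    "BiennialRule",
    "WithinYearRule",
    "GrowthRateSchedule",
    "ScenarioSpec",
    "IntroductionEvent",
    "build_scenario",
    "growth_rate_at",
    "apply_temperature",
    "percent_reduction",
    "SCENARIO_IDS",
    "R_PARENTAL_HIGH",
    "R_PARENTAL_LOW",
    "R_F2",
    "COLONIZATION_DENSITY",
    "DEFAULT_WINTER_EPS",
]

SCENARIO_IDS = ("A", "B", "C", "D", "E")
R_PARENTAL_HIGH = 0.35
R_PARENTAL_LOW = 0.30
R_F2 = 0.30
COLONIZATION_DENSITY = 0.001  # individuals per litre
DEFAULT_WINTER_EPS = 0.1
D_SWITCH_DAY = 165.0  # half-open: [165, 365) carries the second value


class ClassRule:
    """Time-dependent growth-rate rule for one class."""

    def rate(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def switch_times(self, horizon_days: float) -> list[float]:
        """Times in (0, horizon) where the rule's value jumps."""
        return []


@dataclass(frozen=True)
class ConstantRule(ClassRule):
    value: float

    def rate(self, t: float) -> float:
        return self.value


@dataclass(frozen=True)
class BiennialRule(ClassRule):
    """Alternates between two values, holding each for ``hold_years`` years."""

    first: float
    second: float
    hold_years: float = 2.0

    def rate(self, t: float) -> float:
        period = self.hold_years * YEAR_LENGTH
        phase = int(np.floor(t / period)) % 2
        return self.first if phase == 0 else self.second

    def switch_times(self, horizon_days: float) -> list[float]:
        step = self.hold_years * YEAR_LENGTH
        return list(np.arange(step, horizon_days, step))


@dataclass(frozen=True)
class WithinYearRule(ClassRule):
    """Takes ``first`` before ``switch_day`` (day-of-year) and ``second`` after."""

    first: float
    second: float
    switch_day: float = D_SWITCH_DAY

    def rate(self, t: float) -> float:
        return self.first if day_of_year(t) < self.switch_day else self.second

    def switch_times(self, horizon_days: float) -> list[float]:
        out = []
        year_start = 0.0
        while year_start < horizon_days:
            tick = year_start + self.switch_day
            if 0.0 < tick < horizon_days:
                out.append(tick)
            year_start += YEAR_LENGTH
        return out


@dataclass(frozen=True)
class GrowthRateSchedule:
    """Per-class growth-rate schedule r_j(t).

    Explicit rules are stored for the parental species (1, 2), F1-hybrids
    (3) and F2-hybrids (6); the backcross rates (4, 5) are always derived
    as the instantaneous mean of the respective parental rate and the F1
    rate.
    """

    parental_1: ClassRule
    parental_2: ClassRule
    f1: ClassRule
    f2: ClassRule = field(default_factory=lambda: ConstantRule(R_F2))

    def rates(self, t: float) -> np.ndarray:
        r1 = self.parental_1.rate(t)
        r2 = self.parental_2.rate(t)
        r3 = self.f1.rate(t)
        return np.array(
            [r1, r2, r3, 0.5 * (r1 + r3), 0.5 * (r2 + r3), self.f2.rate(t)]
        )

    def switch_times(self, horizon_days: float) -> list[float]:
        ticks: set[float] = set()
        for rule in (self.parental_1, self.parental_2, self.f1, self.f2):
            ticks.update(rule.switch_times(horizon_days))
        return sorted(ticks)


@dataclass(frozen=True)
class IntroductionEvent:
    """Impulse addition of asexual individuals of one class at a given time."""

    time: float
    hybrid_class: HybridClass
    density: float

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("introduction density must be non-negative")


@dataclass
class ScenarioSpec:
    """Complete description of one simulation experiment."""

    id: str
    schedule: GrowthRateSchedule
    initial_state: CommunityState
    introduction_events: list[IntroductionEvent]
    horizon_years: int
    params: ModelParameters
    calendar: SeasonCalendar = field(default_factory=SeasonCalendar)
    # For scenario E the reported window is the century after introduction.
    report_start_year: int = 0

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ValueError(f"unknown scenario id {self.id!r}; expected one of {SCENARIO_IDS}")
        horizon_days = self.horizon_years * YEAR_LENGTH
        for ev in self.introduction_events:
            if not 0.0 <= ev.time <= horizon_days:
                raise ValueError(f"introduction at t={ev.time} outside horizon")

    @property
    def horizon_days(self) -> float:
        return self.horizon_years * YEAR_LENGTH


def build_scenario(
    id: str,
    r3: float = R_PARENTAL_HIGH,
    params: ModelParameters | None = None,
    horizon_years: int | None = None,
    winter_advantage: bool = False,
    winter_eps: float = DEFAULT_WINTER_EPS,
    calendar: SeasonCalendar | None = None,
) -> ScenarioSpec:
    """Assemble a ScenarioSpec for scenario ``id`` in {A..E}.

    ``r3`` is the F1-hybrid intrinsic growth rate (1/day).  With
    ``winter_advantage`` on, the F1 class uses ``winter_eps`` as its
    seasonal amplitude during the winter window (default 0.1, the strongest
    tested advantage); otherwise it shares the baseline amplitude.
    Scenarios A-D start from both parental species at the colonization
    density of 0.001 individuals per litre and run 100 years by default;
    scenario E starts from species 1 alone and introduces species 2 after
    100 years, running 200 years in total.
    """
    if id not in SCENARIO_IDS:
        raise ValueError(f"unknown scenario id {id!r}; expected one of {SCENARIO_IDS}")
    if r3 <= 0:
        raise ValueError("r3 must be positive")
    params = params if params is not None else ModelParameters()
    calendar = calendar if calendar is not None else SeasonCalendar()
    params = replace(
        params,
        eps_winter_F1=winter_eps if winter_advantage else params.eps_base,
    )

    f1 = ConstantRule(r3)
    hi, lo = R_PARENTAL_HIGH, R_PARENTAL_LOW
    if id == "A":
        schedule = GrowthRateSchedule(ConstantRule(hi), ConstantRule(hi), f1)
    elif id == "B":
        schedule = GrowthRateSchedule(ConstantRule(hi), ConstantRule(lo), f1)
    elif id == "C":
        schedule = GrowthRateSchedule(BiennialRule(lo, hi), BiennialRule(hi, lo), f1)
    elif id == "D":
        schedule = GrowthRateSchedule(WithinYearRule(lo, hi), WithinYearRule(hi, lo), f1)
    else:  # E
        schedule = GrowthRateSchedule(ConstantRule(lo), ConstantRule(hi), f1)

    A0 = np.zeros(N_CLASSES)
    events: list[IntroductionEvent] = []
    report_start_year = 0
    if id == "E":
        A0[HybridClass.PARENTAL_1.array_index] = COLONIZATION_DENSITY
        horizon_years = 200 if horizon_years is None else horizon_years
        intro_time = 100 * YEAR_LENGTH
        if intro_time < horizon_years * YEAR_LENGTH:
            events.append(
                IntroductionEvent(intro_time, HybridClass.PARENTAL_2, COLONIZATION_DENSITY)
            )
        report_start_year = 100
    else:
        A0[HybridClass.PARENTAL_1.array_index] = COLONIZATION_DENSITY
        A0[HybridClass.PARENTAL_2.array_index] = COLONIZATION_DENSITY
        horizon_years = 100 if horizon_years is None else horizon_years

    initial = CommunityState(A0, np.zeros(N_CLASSES), np.zeros(N_CLASSES))
    return ScenarioSpec(
        id=id,
        schedule=schedule,
        initial_state=initial,
        introduction_events=events,
        horizon_years=horizon_years,
        params=params,
        calendar=calendar,
        report_start_year=min(report_start_year, horizon_years),
    )


def growth_rate_at(
    schedule: GrowthRateSchedule, j: HybridClass | int, t: float
) -> float:
    """Evaluate r_j(t) for a single class."""
    if t < 0:
        raise ValueError("time must be non-negative")
    return float(schedule.rates(t)[HybridClass(j).array_index])


def apply_temperature(spec: ScenarioSpec, x: float) -> ScenarioSpec:
    """Return a copy of ``spec`` with the annual temperature offset x (degC).

    The offset acts through the Q10 factor q = 2**(x/10) multiplying the
    logistic growth term of every class.
    """
    new_params = replace(spec.params, temp_shift_x=float(x))
    return replace(spec, params=new_params)


def percent_reduction(r3: float, reference: float = R_PARENTAL_HIGH) -> float:
    """Reduction of the F1 growth rate expressed as percent of the parental 0.35."""
    return 100.0 * (reference - r3) / reference
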