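"""Core model: state, parameters, seasonal forcing, mating kernel, ODE right-hand side.

The community consists of six classes of the *Daphnia longispina* species
complex — the two parental species, F1-hybrids, the two backcrosses and
F2-hybrids.  Each class j is tracked through three compartments: asexually
reproducing (parthenogenetic) females A_j, sexually reproducing individuals
S_j, and dormant eggs (ephippia) E_j, all in individuals (or ephippia) per
litre.  Asexual growth is logistic with a shared carrying capacity K, both
growth rate and carrying capacity being modulated by a sinusoidal seasonal
function sigma(t).  Twice a year a fraction of asexuals switches to sexual
reproduction; sexual encounters between the parental species and F1-hybrids
produce ephippia that hatch (two hatchlings each) during a short window in
spring.  A "winter advantage" lowers the seasonal amplitude experienced by
F1-hybrids during winter, representing their better overwinter survival as
parthenogenetic lineages.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "HybridClass",
    "CommunityState",
    "ModelParameters",
    "SeasonCalendar",
    "YEAR_LENGTH",
    "N_CLASSES",
    "day_of_year",
    "seasonal_sigma",
    "class_sigma",
    "switching_rate",
    "hatching_rate",
    "mating_output",
    "temperature_factor",
    "derivatives",
]

YEAR_LENGTH = 365.0
N_CLASSES = 6


class HybridClass(enum.IntEnum):
    """The six genotype classes, indexed 1-6 as in the model equations."""

    PARENTAL_1 = 1
    PARENTAL_2 = 2
    F1_HYBRID = 3
    BACKCROSS_1 = 4  # backcross to parental species 1
    BACKCROSS_2 = 5  # backcross to parental species 2
    F2_HYBRID = 6

    @property
    def array_index(self) -> int:
        """Zero-based position in state vectors."""
        return int(self) - 1


@dataclass
class CommunityState:
    """Densities of the 18 state variables (per litre).

    ``A``, ``S`` and ``E`` are length-6 vectors ordered by class index:
    asexual females, sexual individuals and ephippia respectively.
    """

    A: np.ndarray
    S: np.ndarray
    E: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        for name, vec in (("A", self.A), ("S", self.S), ("E", self.E)):
            if vec.shape != (N_CLASSES,):
                raise ValueError(f"{name} must have shape (6,), got {vec.shape}")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(vec < 0):
                raise ValueError(f"{name} contains negative densities")

    @classmethod
    def zeros(cls) -> "CommunityState":
        return cls(np.zeros(N_CLASSES), np.zeros(N_CLASSES), np.zeros(N_CLASSES))

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "CommunityState":
        y = np.asarray(y, dtype=float)
        if y.shape != (3 * N_CLASSES,):
            raise ValueError(f"state vector must have length 18, got {y.shape}")
        return cls(y[0:6].copy(), y[6:12].copy(), y[12:18].copy())

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.A, self.S, self.E])

    def copy(self) -> "CommunityState":
        return CommunityState(self.A.copy(), self.S.copy(), self.E.copy())


def _default_e() -> np.ndarray:
    return np.array([0.7, 0.7, 0.8, 0.75, 0.75, 0.85])


def _default_h() -> np.ndarray:
    return np.array([0.1, 0.1, 0.05, 0.05, 0.05, 0.05])


@dataclass
class ModelParameters:
    """Model constants.

    Defaults are the published reference values: sexual mortality
    m = 0.15 / day, carrying capacity K = 150 / L, k = 1 ephippium per
    encounter, ephippium production f = 0.14 / day, within-class mating
    fraction c = 0.75, empty-ephippium fractions e_j (hybrid classes
    produce more empty ephippia), hatching rates h_j (hybrid ephippia
    hatch at half the parental rate), switching rate s_max = 0.5 / day
    during the sexual windows and seasonal amplitude eps = 0.7.

    ``eps_winter_F1`` is the amplitude the F1 class experiences during the
    winter window; equal to ``eps_base`` when the winter advantage is off.
    ``temp_shift_x`` is the annual temperature offset in degrees Celsius,
    entering through the Q10 factor ``q = 2**(x/10)`` which scales only the
    logistic growth term.  ``shared_sigma_in_density`` keeps the seasonal
    scaling of the shared carrying-capacity term at the baseline amplitude
    for every class; setting it False uses each class's own sigma there
    (sensitivity check only).
    """

    m: float = 0.15
    K: float = 150.0
    k: float = 1.0
    f: float = 0.14
    c: float = 0.75
    e: np.ndarray = field(default_factory=_default_e)
    h_max: np.ndarray = field(default_factory=_default_h)
    s_max: float = 0.5
    eps_base: float = 0.7
    eps_winter_F1: float = 0.7
    temp_shift_x: float = 0.0
    shared_sigma_in_density: bool = True

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        self.h_max = np.asarray(self.h_max, dtype=float)
        if self.e.shape != (N_CLASSES,) or self.h_max.shape != (N_CLASSES,):
            raise ValueError("e and h_max must be length-6 vectors")
        for name in ("m", "K", "k", "f", "s_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")
        if np.any(self.e < 0) or np.any(self.e > 1):
            raise ValueError("empty-ephippium fractions e must lie in [0, 1]")
        if np.any(self.h_max < 0):
            raise ValueError("hatching rates must be non-negative")
        for name in ("eps_base", "eps_winter_F1"):
            eps = getattr(self, name)
            if not 0.0 <= eps < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not math.isfinite(self.temp_shift_x):
            raise ValueError("temp_shift_x must be finite")

    def with_(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)

    @property
    def q(self) -> float:
        return temperature_factor(self.temp_shift_x)


Window = tuple[float, float]


@dataclass
class SeasonCalendar:
    """Day-of-year windows driving the piecewise-constant forcing.

    Windows are half-open ``[start, end)`` intervals of day-of-year, so a
    period printed as "days a-b" becomes ``[a-1, b)``: each printed day is a
    unit-length interval.  Defaults: two 15-day sexual windows in May and
    September (printed days 151-165 and 273-287), a 2-day hatching window in
    spring (printed days 119-120) and a 120-day winter from 1 November to the
    end of February, wrapping over new year as two intervals.
    """

    year_length: float = YEAR_LENGTH
    sexual_windows: tuple[Window, ...] = ((150.0, 165.0), (272.0, 287.0))
    hatching_window: Window = (118.0, 120.0)
    winter_windows: tuple[Window, ...] = ((304.0, 365.0), (0.0, 59.0))

    def __post_init__(self) -> None:
        for start, end in (*self.sexual_windows, self.hatching_window, *self.winter_windows):
            if not (0.0 <= start < end <= self.year_length):
                raise ValueError(
                    f"window [{start}, {end}) must lie within [0, {self.year_length}]"
                )

    def in_sexual_window(self, doy: float) -> bool:
        return any(a <= doy < b for a, b in self.sexual_windows)

    def in_hatching_window(self, doy: float) -> bool:
        a, b = self.hatching_window
        return a <= doy < b

    def in_winter(self, doy: float) -> bool:
        return any(a <= doy < b for a, b in self.winter_windows)

    def window_edges(self) -> list[float]:
        """Sorted unique day-of-year values where any forcing switches."""
        edges: set[float] = set()
        for a, b in (*self.sexual_windows, self.hatching_window, *self.winter_windows):
            edges.add(a)
            edges.add(b)
        edges.discard(self.year_length)  # the year boundary is added separately
        return sorted(edges)


def day_of_year(t: float) -> float:
    """Map simulation time in days to a day-of-year position in [0, 365).

    The model year has exactly 365 days; no leap years.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    return float(t) % YEAR_LENGTH


def seasonal_sigma(t, eps: float):
    """Sinusoidal seasonal multiplier sigma(t) = (1 - eps*cos(2*pi*t/365)) / (1 + eps).

    Scales both growth rate and carrying capacity; equals 1 at mid-year
    (peak season) and (1 - eps)/(1 + eps) at the turn of the year.
    Accepts scalar or array ``t``.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"eps must lie in [0, 1), got {eps}")
    t = np.asarray(t, dtype=float)
    out = (1.0 - eps * np.cos(2.0 * np.pi * t / YEAR_LENGTH)) / (1.0 + eps)
    return out if out.ndim else float(out)


def class_sigma(
    t: float,
    j: HybridClass | int,
    params: ModelParameters,
    calendar: SeasonCalendar,
) -> float:
    """Seasonal multiplier experienced by class j at time t.

    Every class follows the baseline amplitude except F1-hybrids, which use
    the (lower) winter amplitude while day-of-year is inside the winter
    window — their overwinter advantage as parthenogenetic lineages.
    """
    j = HybridClass(j)
    if j is HybridClass.F1_HYBRID and calendar.in_winter(day_of_year(t)):
        return seasonal_sigma(t, params.eps_winter_F1)
    return seasonal_sigma(t, params.eps_base)


def switching_rate(t: float, calendar: SeasonCalendar, s_max: float) -> float:
    """Rate s(t) at which asexuals switch to sexual reproduction.

    Equals ``s_max`` inside either sexual window (May / September), zero
    otherwise; identical for all classes.
    """
    if s_max < 0:
        raise ValueError("s_max must be non-negative")
    return s_max if calendar.in_sexual_window(day_of_year(t)) else 0.0


def hatching_rate(
    t: float,
    j: HybridClass | int,
    calendar: SeasonCalendar,
    h_max: Sequence[float],
) -> float:
    """Hatching rate h_j(t) of class-j ephippia: h_max[j] in the spring
    hatching window, zero otherwise."""
    j = HybridClass(j)
    h_max = np.asarray(h_max, dtype=float)
    if np.any(h_max < 0):
        raise ValueError("hatching rates must be non-negative")
    return float(h_max[j.array_index]) if calendar.in_hatching_window(day_of_year(t)) else 0.0


def mating_output(S1: float, S2: float, S3: float, c: float) -> np.ndarray:
    """Per-class ephippium-production propensities phi_j from sexual encounters.

    Only the parental species (classes 1, 2) and F1-hybrids (class 3) take
    part in sexual reproduction.  A fraction ``c`` of their sexual
    individuals mates strictly within its own class; the remaining ``1 - c``
    mates at random across the three classes.  With T = S1 + S2 + S3:

    * phi_1, phi_2 = S_j (S_j + c (T - S_j)) / (2 T)  — within-species matings,
    * phi_3 = (1-c) S1 S2 / T                          — new F1-hybrids,
    * phi_4 = (1-c) S1 S3 / T, phi_5 = (1-c) S2 S3 / T — backcrosses,
    * phi_6 = S3 (S3 + c (S1 + S2)) / (2 T)            — F2-hybrids.

    The within-class fraction of F1 x F1 matings also yields class-6
    ephippia, which is why phi_6 keeps the full assortative term.  Every
    encounter pairs one female with one male (equal sex ratio), so the
    outputs conserve sum(phi) = T / 2 for any c.  With no sexual
    individuals present (T = 0) all outputs are zero.
    """
    if S1 < 0 or S2 < 0 or S3 < 0:
        raise ValueError("sexual densities must be non-negative")
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must lie in [0, 1]")
    T = S1 + S2 + S3
    phi = np.zeros(N_CLASSES)
    if T == 0.0:
        return phi
    phi[0] = S1 * (S1 + c * (T - S1)) / (2.0 * T)
    phi[1] = S2 * (S2 + c * (T - S2)) / (2.0 * T)
    phi[2] = (1.0 - c) * S1 * S2 / T
    phi[3] = (1.0 - c) * S1 * S3 / T
    phi[4] = (1.0 - c) * S2 * S3 / T
    phi[5] = S3 * (S3 + c * (S1 + S2)) / (2.0 * T)
    return phi


def temperature_factor(x: float) -> float:
    """Q10-derived growth multiplier q = 2**(x/10) for a temperature offset x (degC).

    A 10 degC warming doubles the intrinsic growth rate; the factor scales
    only the logistic growth term, not switching, mortality, hatching or
    ephippium production.
    """
    if not math.isfinite(x):
        raise ValueError("temperature offset must be finite")
    return float(2.0 ** (x / 10.0))


def derivatives(
    t: float,
    state: CommunityState | np.ndarray,
    params: ModelParameters,
    calendar: SeasonCalendar,
    r_of_t: Callable[[float], np.ndarray],
    q: float | None = None,
) -> np.ndarray:
    """Right-hand side of the 18-variable ODE system, as a flat vector.

    For each class j:

    * dA_j/dt = q r_j(t) sigma_j(t) A_j (1 - sum_i (A_i + S_i) / (sigma(t) K))
      - s(t) A_j + 2 h_j(t) E_j   (each ephippium holds two embryos),
    * dS_j/dt = s(t) A_j - m S_j,
    * dE_j/dt = (1 - e_j) f phi_j - h_j(t) E_j.

    ``r_of_t`` must return the length-6 vector of instantaneous intrinsic
    growth rates.  The density-dependence bracket is shared by all classes
    and (by default) uses the baseline seasonal amplitude even when the F1
    winter advantage gives class 3 its own sigma in the growth term.
    """
    if isinstance(state, CommunityState):
        y = state.to_vector()
    else:
        y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state at t={t}")
    if q is None:
        q = params.q

    A = y[0:6]
    S = y[6:12]
    E = y[12:18]

    doy = day_of_year(t)
    sigma_base = seasonal_sigma(t, params.eps_base)
    sigma_j = np.full(N_CLASSES, sigma_base)
    if calendar.in_winter(doy):
        sigma_j[HybridClass.F1_HYBRID.array_index] = seasonal_sigma(t, params.eps_winter_F1)
    sigma_density = sigma_base if params.shared_sigma_in_density else sigma_j

    r = np.asarray(r_of_t(t), dtype=float)
    s = params.s_max if calendar.in_sexual_window(doy) else 0.0
    if calendar.in_hatching_window(doy):
        h = params.h_max
    else:
        h = np.zeros(N_CLASSES)

    # tiny integrator-induced negatives are treated as zero for mating
    phi = mating_output(max(S[0], 0.0), max(S[1], 0.0), max(S[2], 0.0), params.c)

    crowding = 1.0 - np.sum(A + S) / (sigma_density * params.K)
    dA = q * r * sigma_j * A * crowding - s * A + 2.0 * h * E
    dS = s * A - params.m * S
    dE = (1.0 - params.e) * params.f * params.k * phi - h * E
    return np.concatenate([dA, dS, dE])
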