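"""Density- and frequency-dependent vital rates.

Unowned cat survival declines with abundance relative to carrying
capacity, free-roaming kitten survival declines with the proportion of
intact adults (hormone-mediated aggression), shelter adoption declines
as the owned population approaches its carrying capacity, and
off-street adoption / surrender of free-roaming cats respond to both
the owned and free-roaming population states.

The literature prints three mutually inconsistent survival
parameterizations, exposed here as selectable variants:

``calibrated`` (default)
    ``a * exp(-b * N/K)`` with ``b = ln(a / 0.5)`` so adult survival is
    exactly 0.5 at carrying capacity — the only calibration constraint
    stated explicitly.
``eq14_16``
    The composite forms ``0.82 exp(-0.476 e^{0.0482 N/K})``
    (free-roaming) and ``0.65 exp(-3.812 e^{-2.676 N/K})`` (feral).
    Note the feral form *increases* with density; it is implemented
    verbatim.
``table1``
    Density-unit decays ``0.82 exp(-0.475669 N/area)`` and
    ``0.65 exp(-10.0719 N/area)``, with N interpreted as the female
    count (set ``table1_total_count`` to use the doubled count).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import InvalidConfiguration

__all__ = [
    "DensityDependenceSpec",
    "PopulationSnapshot",
    "adult_unowned_survival",
    "juvenile_freeroaming_survival",
    "freeroaming_juvenile_six_month",
    "juvenile_feral_survival",
    "feral_juvenile_six_month",
    "shelter_adoption_rate",
    "offstreet_adoption_rate",
    "surrender_rate",
    "logistic",
]

VARIANTS = ("calibrated", "table1", "eq14_16")
JUVENILE_RULES = ("sqrt_adult", "full_adult")

#: Stage-major ordering of the population vector: 4 stages (intact
#: juvenile, intact adult, sterile juvenile, sterile adult) x 4 states
#: (owned, shelter, free-roaming, feral).
STAGES = ("intact_juvenile", "intact_adult", "sterile_juvenile", "sterile_adult")
STATES = ("owned", "shelter", "freeroaming", "feral")


def logistic(x: float) -> float:
    """Numerically stable logistic 1 / (1 + e^-x)."""
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass(frozen=True)
class DensityDependenceSpec:
    """Selected survival variant and its curve coefficients."""

    variant: str = "calibrated"
    juvenile_rule: str = "sqrt_adult"
    table1_total_count: bool = False
    # eq14_16 composite coefficients
    eq14_outer: float = 0.476
    eq14_inner: float = 0.0482
    eq16_outer: float = 3.812
    eq16_inner: float = 2.676
    # table1 density-unit decay coefficients (per cat/ha)
    table1_decay_freeroaming: float = 0.475669
    table1_decay_feral: float = 10.0719
    # calibrated variant: adult survival at carrying capacity
    survival_at_k: float = 0.5

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidConfiguration(
                f"unknown survival variant {self.variant!r}; choose from {VARIANTS}"
            )
        if self.juvenile_rule not in JUVENILE_RULES:
            raise InvalidConfiguration(
                f"unknown juvenile_rule {self.juvenile_rule!r}; "
                f"choose from {JUVENILE_RULES}"
            )
        if not 0.0 < self.survival_at_k < 1.0:
            raise InvalidConfiguration("survival_at_k must be in (0, 1)")


@dataclass(frozen=True)
class PopulationSnapshot:
    """Aggregates of the 16-entry female population vector used by the
    density-dependent rates."""

    owned: float
    shelter: float
    freeroaming: float
    feral: float
    freeroaming_intact_adults: float
    freeroaming_sterile_adults: float

    @classmethod
    def from_vector(cls, n: np.ndarray) -> "PopulationSnapshot":
        n = np.asarray(n, dtype=float)
        if n.shape != (16,):
            raise ValueError(f"population vector must have 16 entries, got {n.shape}")
        if np.any(n < 0):
            raise ValueError("population vector entries must be >= 0")
        m = n.reshape(4, 4)  # stages x states
        totals = m.sum(axis=0)
        return cls(
            owned=float(totals[0]),
            shelter=float(totals[1]),
            freeroaming=float(totals[2]),
            feral=float(totals[3]),
            freeroaming_intact_adults=float(m[1, 2]),
            freeroaming_sterile_adults=float(m[3, 2]),
        )

    @property
    def proportion_intact_freeroaming(self) -> float:
        """Intact fraction of adult free-roaming cats; 0 for an empty group."""
        total = self.freeroaming_intact_adults + self.freeroaming_sterile_adults
        if total <= 0:
            return 0.0
        return self.freeroaming_intact_adults / total


def adult_unowned_survival(
    n: float,
    k: float,
    spec: DensityDependenceSpec,
    state: str,
    intercept: float | None = None,
    area_ha: float | None = None,
) -> float:
    """Annual density-dependent survival of adult unowned cats.

    ``state`` is ``"freeroaming"`` or ``"feral"``; ``intercept``
    overrides the zero-density maximum (0.82 / 0.65).  ``area_ha`` is
    required by the ``table1`` variant, whose decay operates on
    density (N / area) rather than the ratio N/K.
    """
    if state not in ("freeroaming", "feral"):
        raise InvalidConfiguration(f"state must be freeroaming or feral, got {state!r}")
    if k <= 0:
        raise InvalidConfiguration("carrying capacity must be > 0")
    if n < 0:
        raise InvalidConfiguration("abundance must be >= 0")
    a = intercept if intercept is not None else (
        0.82 if state == "freeroaming" else 0.65
    )
    x = n / k
    if spec.variant == "calibrated":
        if a <= 0.0:
            return 0.0
        if x == 1.0:  # the calibration point itself, exact by construction
            return spec.survival_at_k
        b = math.log(a / spec.survival_at_k)
        return _clamp01(a * math.exp(-b * x))
    if spec.variant == "eq14_16":
        if state == "freeroaming":
            inner = spec.eq14_inner * x
            if inner > 700.0:  # e^inner overflows; survival underflows to 0
                return 0.0
            return _clamp01(a * math.exp(-spec.eq14_outer * math.exp(inner)))
        return _clamp01(a * math.exp(-spec.eq16_outer * math.exp(-spec.eq16_inner * x)))
    # table1: decay in cats/ha
    if area_ha is None or area_ha <= 0:
        raise InvalidConfiguration("table1 variant requires a positive area_ha")
    density = (2.0 * n if spec.table1_total_count else n) / area_ha
    decay = (
        spec.table1_decay_freeroaming
        if state == "freeroaming"
        else spec.table1_decay_feral
    )
    return _clamp01(a * math.exp(-decay * density))


def freeroaming_juvenile_six_month(
    proportion_intact: float, slope: float = 0.587, intercept: float = 0.907
) -> float:
    """Six-month survival of free-roaming kittens vs the intact fraction
    of adult free-roaming cats, clamped to [0, 1]."""
    if not 0.0 <= proportion_intact <= 1.0:
        raise InvalidConfiguration("proportion_intact must be in [0, 1]")
    return _clamp01(-slope * proportion_intact + intercept)


def _compose_annual(six_month: float, adult_annual: float, rule: str) -> float:
    """Annual kitten survival: first 6 months at the kitten rate, the
    second half-year at the adult rate (sqrt of annual adult survival),
    or at the full annual adult rate under the published table's form."""
    if rule == "sqrt_adult":
        return _clamp01(six_month * math.sqrt(adult_annual))
    if rule == "full_adult":
        return _clamp01(six_month * adult_annual)
    raise InvalidConfiguration(f"unknown juvenile rule {rule!r}")


def juvenile_freeroaming_survival(
    proportion_intact: float,
    adult_annual: float,
    rule: str = "sqrt_adult",
    slope: float = 0.587,
    intercept: float = 0.907,
) -> float:
    """Annual survival of free-roaming kittens: the frequency-dependent
    six-month rate composed with the adult survival for the second
    half-year."""
    if not 0.0 <= adult_annual <= 1.0:
        raise InvalidConfiguration("adult_annual must be in [0, 1]")
    six = freeroaming_juvenile_six_month(proportion_intact, slope, intercept)
    return _compose_annual(six, adult_annual, rule)


def feral_juvenile_six_month(
    n: float,
    k: float,
    spec: DensityDependenceSpec,
    intercept: float = 0.25,
    adult_intercept: float = 0.65,
    area_ha: float | None = None,
) -> float:
    """Six-month survival of feral kittens: the adult density-dependent
    curve rescaled to the 0.25 kitten intercept."""
    if adult_intercept < 0:
        raise InvalidConfiguration("adult_intercept must be >= 0")
    if adult_intercept == 0.0:  # adult curve identically zero
        return 0.0
    adult = adult_unowned_survival(
        n, k, spec, "feral", intercept=adult_intercept, area_ha=area_ha
    )
    return _clamp01(intercept * adult / adult_intercept)


def juvenile_feral_survival(
    n: float,
    k: float,
    spec: DensityDependenceSpec,
    adult_annual: float | None = None,
    rule: str | None = None,
    intercept: float = 0.25,
    adult_intercept: float = 0.65,
    area_ha: float | None = None,
) -> float:
    """Annual survival of feral kittens: density-dependent six-month
    curve composed with the adult rate for the second half-year."""
    if adult_annual is None:
        adult_annual = adult_unowned_survival(
            n, k, spec, "feral", intercept=adult_intercept, area_ha=area_ha
        )
    six = feral_juvenile_six_month(n, k, spec, intercept, adult_intercept, area_ha)
    return _compose_annual(six, adult_annual, rule or spec.juvenile_rule)


def shelter_adoption_rate(
    n_owned: float, k_owned: float, slope: float = -12.0, intercept: float = 12.0
) -> float:
    """Annual probability a shelter cat is adopted.

    Logistic in the owned population relative to its carrying capacity;
    0.5 when owned cats are at carrying capacity, near 1 when homes are
    empty, near 0 when the owned population is saturated.
    """
    if k_owned <= 0:
        raise InvalidConfiguration("owned carrying capacity must be > 0")
    return logistic(slope * (n_owned / k_owned) + intercept)


def offstreet_adoption_rate(
    n_owned: float,
    k_owned: float,
    n_free: float,
    k_free: float,
    decay: float = 1.20397,
    avail_slope: float = 3.87637,
    avail_intercept: float = -5.0,
) -> float:
    """Annual probability a free-roaming cat is adopted off the street.

    Product of the owner-demand decay ``exp(-decay * N_o/K_o)`` and the
    availability logistic in ``N_f/K_f``.
    """
    if k_owned <= 0 or k_free <= 0:
        raise InvalidConfiguration("carrying capacities must be > 0")
    demand = math.exp(-decay * (n_owned / k_owned))
    availability = logistic(avail_slope * (n_free / k_free) + avail_intercept)
    return _clamp01(demand * availability)


def surrender_rate(
    n_free: float,
    k_free: float,
    slope: float = 0.1671,
    intercept: float = -0.5858,
    avail_slope: float = 3.87637,
    avail_intercept: float = -5.0,
) -> float:
    """Annual probability a free-roaming cat is surrendered to a shelter.

    Product of two logistics in ``N_f/K_f``: surrender pressure and
    availability; monotone increasing in free-roaming abundance.
    """
    if k_free <= 0:
        raise InvalidConfiguration("free-roaming carrying capacity must be > 0")
    x = n_free / k_free
    return _clamp01(
        logistic(slope * x + intercept) * logistic(avail_slope * x + avail_intercept)
    )
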