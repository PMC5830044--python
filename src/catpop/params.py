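"""City-level parameterization of the urban cat population model.

Turns the three census-derived inputs for a city (latitude, number of
dwellings, urban area) into the full set of demographic vital rates,
transition constants, and state-specific carrying capacities that drive
the projection model.  All constants default to the published Canadian
parameterization and every one of them can be overridden from a config
file, so city-specific refinements slot in without code changes.

Units: survival, sterilization and transition entries are annual
probabilities; fecundities are female kittens per female per year;
carrying capacities are female counts (a 1:1 sex ratio is assumed when
reporting both-sex abundances).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "CityInputs",
    "CarryingCapacities",
    "BreedingSeasonParams",
    "ParameterSet",
    "LossRates",
    "STERILIZATION_PRESETS",
    "breeding_season_length",
    "litters_per_year",
    "carrying_capacity_owned",
    "carrying_capacity_shelter",
    "carrying_capacity_unowned",
    "derive_loss_rate",
    "derive_recovery_rates",
    "build_parameter_set",
]

# Geometric-mean densities (cats/ha, both sexes) of unowned cats from the
# compiled literature: exp(mean of log densities).
DEFAULT_FREEROAMING_DENSITY = math.exp(-0.752664)  # 0.4711098 cats/ha
DEFAULT_FERAL_DENSITY = math.exp(-2.536883)  # 0.07911264 cats/ha

#: Proportion of cats entering shelters that are euthanized or remain
#: homeless (39.9% euthanized + 12% without a home).
SHELTER_EUTHANASIA_FRACTION = 0.519

#: Mean pubescent age in days; kittens breed only in the post-pubertal
#: fraction of their first year.
PUBESCENT_DAY = 212.0


class InvalidConfiguration(ValueError):
    """A city input or parameter override violates its constraints."""


@dataclass(frozen=True)
class CityInputs:
    """Census-level inputs describing one urban area.

    Parameters
    ----------
    latitude : float
        Decimal degrees north, in (-90, 90).
    dwellings : float
        Number of human dwellings in the urban area.
    area_ha : float
        Urban land area in hectares.
    freeroaming_density, feral_density : float
        Equilibrium densities of unowned cats (both sexes, cats/ha) used
        to derive carrying capacities; default to the geometric means of
        published density records.
    shelter_capacity : float
        Number of shelter spaces for cats.
    mean_length_of_stay : float
        Average shelter length of stay in days.
    proportion_dwellings_with_cats, cats_per_dwelling : float
        Ownership statistics; defaults are Canadian polling values
        (37.7% of dwellings, 1.85 cats each).
    """

    latitude: float
    dwellings: float
    area_ha: float
    freeroaming_density: float = DEFAULT_FREEROAMING_DENSITY
    feral_density: float = DEFAULT_FERAL_DENSITY
    shelter_capacity: float = 187.0
    mean_length_of_stay: float = 30.0
    proportion_dwellings_with_cats: float = 0.377
    cats_per_dwelling: float = 1.85

    def __post_init__(self) -> None:
        if not -90.0 < self.latitude < 90.0:
            raise InvalidConfiguration(f"latitude {self.latitude} outside (-90, 90)")
        if self.dwellings < 0:
            raise InvalidConfiguration("dwellings must be >= 0")
        if self.area_ha <= 0:
            raise InvalidConfiguration("area_ha must be > 0")
        if self.freeroaming_density <= 0 or self.feral_density <= 0:
            raise InvalidConfiguration("unowned cat densities must be > 0")
        if self.mean_length_of_stay <= 0:
            raise InvalidConfiguration("mean_length_of_stay must be > 0")
        if self.shelter_capacity < 0:
            raise InvalidConfiguration("shelter_capacity must be >= 0")


@dataclass(frozen=True)
class CarryingCapacities:
    """Female carrying capacities per state (1:1 sex ratio assumed)."""

    owned: float
    shelter: float  # annual female throughput the shelter can accommodate
    freeroaming: float
    feral: float

    def __post_init__(self) -> None:
        for name in ("owned", "shelter", "freeroaming", "feral"):
            if getattr(self, name) < 0:
                raise InvalidConfiguration(f"carrying capacity {name} must be >= 0")


@dataclass(frozen=True)
class BreedingSeasonParams:
    """Four-parameter logistic of breeding season length vs latitude.

    ``a`` is fixed at 365 days so that low-latitude breeding is
    year-round; ``b`` is the high-latitude asymptote, ``c`` the slope per
    degree, and ``d`` the inflection latitude.  ``days_per_litter`` is
    65 days gestation + 84 days weaning.
    """

    a: float = 365.0
    b: float = 170.3539
    c: float = 0.1351
    d: float = 31.8447
    days_per_litter: float = 149.0


def breeding_season_length(
    latitude: float, params: BreedingSeasonParams | None = None
) -> float:
    """Breeding season length in days at a given latitude.

    Evaluates the 4-parameter logistic ``a + (b - a) / (1 + exp(c (d - x)))``
    which declines from near-365 days at the equator to about ``b`` days
    at high northern latitudes.
    """
    p = params or BreedingSeasonParams()
    if not -90.0 < latitude < 90.0:
        raise InvalidConfiguration(f"latitude {latitude} outside (-90, 90)")
    return p.a + (p.b - p.a) / (1.0 + math.exp(p.c * (p.d - latitude)))


def litters_per_year(
    season_days: float, params: BreedingSeasonParams | None = None
) -> float:
    """Mean litters per female per year: season length / 149 days per litter."""
    p = params or BreedingSeasonParams()
    if season_days < 0:
        raise InvalidConfiguration("season_days must be >= 0")
    return season_days / p.days_per_litter


def carrying_capacity_owned(
    dwellings: float,
    proportion_with_cats: float = 0.377,
    cats_per_dwelling: float = 1.85,
) -> float:
    """Female carrying capacity of owned cats from dwelling counts."""
    if dwellings < 0:
        raise InvalidConfiguration("dwellings must be >= 0")
    return proportion_with_cats * cats_per_dwelling * dwellings / 2.0


def carrying_capacity_shelter(capacity: float, stay_days: float) -> float:
    """Annual female shelter throughput: spaces x (365 / length of stay) / 2."""
    if stay_days <= 0:
        raise InvalidConfiguration("length of stay must be > 0")
    if capacity < 0:
        raise InvalidConfiguration("shelter capacity must be >= 0")
    return capacity * (365.0 / stay_days) / 2.0


def carrying_capacity_unowned(density: float, area_ha: float) -> float:
    """Female carrying capacity of an unowned class: density x area / 2."""
    if density < 0 or area_ha < 0:
        raise InvalidConfiguration("density and area must be >= 0")
    return density * area_ha / 2.0


@dataclass(frozen=True)
class LossRates:
    """Derivation chain for the annual loss of owned cats.

    The cumulative probability of loss follows ``L = a * log(t + 1)``;
    with 15% of cats lost over 5 years, ``a = 0.15 / log(6)`` and the
    annual loss is ``a * log(2) ~= 0.058``.  Only the fraction of lost
    cats that are returned via shelters (6 of 69) enters the model as
    the owned -> free-roaming loss rate.
    """

    coefficient: float
    annual: float
    shelter_routed: float


def derive_loss_rate(
    cumulative: float = 0.15,
    horizon_years: float = 5.0,
    shelter_return_fraction: float = 6.0 / 69.0,
) -> LossRates:
    """Solve the logarithmic loss model for the annual loss probability."""
    a = cumulative / math.log(horizon_years + 1.0)
    annual = a * math.log(2.0)
    return LossRates(
        coefficient=a, annual=annual, shelter_routed=annual * shelter_return_fraction
    )


def derive_recovery_rates(
    y_identified: float = 0.385,
    y_unidentified: float = 0.018,
    identified_fraction: float = 0.19,
    intact_odds: float = 0.25 / 0.57,
) -> tuple[float, float]:
    """Return-to-owner probabilities (intact, sterile) for shelter cats.

    ``c_sterile = y_i * i + y_n * (1 - i)`` combines return rates for
    cats with and without identification; intact cats are recovered at
    the relative odds ``o = 0.25 / 0.57`` of sterilized cats.
    """
    c_sterile = y_identified * identified_fraction + y_unidentified * (
        1.0 - identified_fraction
    )
    c_intact = intact_odds * c_sterile
    return c_intact, c_sterile


#: Annual sterilization probabilities for unowned cats.  The published
#: parameter table and the accompanying text disagree; both sets are
#: provided and "table1" is the default.
STERILIZATION_PRESETS: dict[str, dict[str, float]] = {
    "table1": {
        "n0_freeroaming": 0.05,
        "n1_freeroaming": 0.125,
        "n0_feral": 0.01,
        "n1_feral": 0.025,
    },
    "text": {
        "n0_freeroaming": 0.01,
        "n1_freeroaming": 0.025,
        "n0_feral": 0.001,
        "n1_feral": 0.0025,
    },
}

_PROBABILITY_FIELDS = (
    "s0_owned",
    "s1_owned",
    "s0_shelter",
    "s1_shelter",
    "surv_max_freeroaming",
    "surv_max_feral",
    "juv_feral_intercept",
    "n0_owned",
    "n1_owned",
    "n0_shelter",
    "n1_shelter",
    "n0_freeroaming",
    "n1_freeroaming",
    "n0_feral",
    "n1_feral",
    "relinquishment",
    "loss",
    "abandonment",
    "kitten_feral",
    "feral_surrender",
    "recovery_intact",
    "recovery_sterile",
    "juvenile_breeding_fraction",
)


@dataclass(frozen=True)
class ParameterSet:
    """Every lower-level rate of the model — the theta of the sensitivity
    analysis.

    Survival entries for owned and shelter cats are static annual
    probabilities (shelter survival already discounts euthanasia);
    unowned survival is density dependent and parameterized here only by
    its maximum (zero-density intercept).  Fecundities are female
    kittens per female per year, the product of litter size / 2 and the
    latitude-driven litters per year ``k``; juveniles breed at the
    pre-pubertal-discounted fraction.  Transition constants follow the
    published transition table; slopes/intercepts parameterize the
    density-dependent adoption, off-street adoption and surrender
    curves.
    """

    # --- survival ---
    s0_owned: float = 0.7
    s1_owned: float = 0.8
    s0_shelter: float = 0.7 * (1.0 - SHELTER_EUTHANASIA_FRACTION)
    s1_shelter: float = 0.8 * (1.0 - SHELTER_EUTHANASIA_FRACTION)
    surv_max_freeroaming: float = 0.82  # zero-density adult survival intercept
    surv_max_feral: float = 0.65
    juv_feral_intercept: float = 0.25  # 6-month feral kitten intercept
    freq_dep_slope: float = 0.587  # free-roaming kitten survival vs prop. intact
    freq_dep_intercept: float = 0.907

    # --- reproduction ---
    litter_owned: float = 3.8  # kittens (both sexes) per litter
    litter_freeroaming: float = 3.6
    litter_feral: float = 3.5
    litters_per_year: float = 1.0  # k, derived from latitude
    juvenile_breeding_fraction: float = (365.0 - PUBESCENT_DAY) / 365.0

    # --- sterilization ---
    n0_owned: float = 0.7
    n1_owned: float = 0.1
    n0_shelter: float = 1.0
    n1_shelter: float = 1.0
    n0_freeroaming: float = 0.05
    n1_freeroaming: float = 0.125
    n0_feral: float = 0.01
    n1_feral: float = 0.025

    # --- transitions ---
    relinquishment: float = 0.012  # r: owned -> shelter
    loss: float = 0.0049  # l: owned -> free-roaming via being lost
    abandonment: float = 0.05  # a: owned -> free-roaming
    kitten_feral: float = 0.05  # ff: free-roaming kittens becoming feral
    feral_surrender: float = 0.0001  # fs: feral -> shelter
    recovery_intact: float = 0.03847807  # c for intact shelter cats
    recovery_sterile: float = 0.08773  # c for sterile shelter cats
    adopt_slope: float = -12.0  # shelter adoption logistic vs N_o/K_o
    adopt_intercept: float = 12.0
    offstreet_decay: float = 1.20397  # -ln(0.3): owner-seeking decay vs N_o/K_o
    avail_slope: float = 3.87637  # availability logistic vs N_f/K_f
    avail_intercept: float = -5.0
    surrender_slope: float = 0.1671  # surrender logistic vs N_f/K_f
    surrender_intercept: float = -0.5858

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfiguration(f"{name} = {v} outside [0, 1]")
        if self.litters_per_year < 0:
            raise InvalidConfiguration("litters_per_year must be >= 0")
        for name in ("litter_owned", "litter_freeroaming", "litter_feral"):
            if getattr(self, name) < 0:
                raise InvalidConfiguration(f"{name} must be >= 0")
        outflow = self.relinquishment + self.loss + self.abandonment
        if outflow > 1.0:
            raise InvalidConfiguration(f"owned outflow r + l + a = {outflow} > 1")

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True)

    # Convenience accessors used when building state-specific blocks.
    def survival_static(self, state: str) -> tuple[float, float] | None:
        """(s0, s1) for the density-independent states, else None."""
        if state == "owned":
            return self.s0_owned, self.s1_owned
        if state == "shelter":
            return self.s0_shelter, self.s1_shelter
        return None

    def litter_size(self, state: str) -> float:
        return {
            "owned": self.litter_owned,
            "shelter": 0.0,
            "freeroaming": self.litter_freeroaming,
            "feral": self.litter_feral,
        }[state]

    def fecundity(self, state: str) -> tuple[float, float]:
        """(f0, f1): female kittens per female per year for a state."""
        f1 = self.litter_size(state) / 2.0 * self.litters_per_year
        return self.juvenile_breeding_fraction * f1, f1

    def sterilization(self, state: str) -> tuple[float, float]:
        return {
            "owned": (self.n0_owned, self.n1_owned),
            "shelter": (self.n0_shelter, self.n1_shelter),
            "freeroaming": (self.n0_freeroaming, self.n1_freeroaming),
            "feral": (self.n0_feral, self.n1_feral),
        }[state]


def build_parameter_set(
    city: CityInputs,
    overrides: Mapping[str, float] | None = None,
    sterilization_set: str = "table1",
    use_derived_loss: bool = False,
    season: BreedingSeasonParams | None = None,
) -> tuple[ParameterSet, CarryingCapacities]:
    """Assemble the full parameter set and carrying capacities for a city.

    Starts from the published defaults, derives the latitude-dependent
    litters per year, the loss and recovery rates, and the four carrying
    capacities, then applies user overrides.  Unknown override names and
    out-of-range probabilities raise :class:`InvalidConfiguration`.
    """
    if sterilization_set not in STERILIZATION_PRESETS:
        raise InvalidConfiguration(
            f"unknown sterilization_set {sterilization_set!r}; "
            f"choose from {sorted(STERILIZATION_PRESETS)}"
        )
    k = litters_per_year(breeding_season_length(city.latitude, season), season)
    c_intact, c_sterile = derive_recovery_rates()
    values: dict[str, float] = {
        "litters_per_year": k,
        "recovery_intact": c_intact,
        "recovery_sterile": c_sterile,
        **STERILIZATION_PRESETS[sterilization_set],
    }
    if use_derived_loss:
        values["loss"] = derive_loss_rate().shelter_routed
    if overrides:
        valid = {f.name for f in dataclasses.fields(ParameterSet)}
        unknown = set(overrides) - valid
        if unknown:
            raise InvalidConfiguration(
                f"unknown parameter override(s): {sorted(unknown)}"
            )
        values.update(overrides)
    params = ParameterSet(**values)
    caps = CarryingCapacities(
        owned=carrying_capacity_owned(
            city.dwellings, city.proportion_dwellings_with_cats, city.cats_per_dwelling
        ),
        shelter=carrying_capacity_shelter(
            city.shelter_capacity, city.mean_length_of_stay
        ),
        freeroaming=carrying_capacity_unowned(city.freeroaming_density, city.area_ha),
        feral=carrying_capacity_unowned(city.feral_density, city.area_ha),
    )
    return params, caps
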