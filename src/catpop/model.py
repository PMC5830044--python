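"""Model/Results interface over the projection machinery.

``UrbanCatPopulationModel`` is constructed from city-level inputs and
``fit()`` iterates the density-dependent projection to its steady
state, returning an ``UrbanCatPopulationResults`` that carries the
equilibrium abundances, convergence diagnostics, a ``summary()`` table,
and elasticity analysis of equilibrium abundance.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
import pandas as pd

from . import sensitivity as _sens
from .params import (
    BreedingSeasonParams,
    CarryingCapacities,
    CityInputs,
    ParameterSet,
    build_parameter_set,
)
from .projection import (
    DEFAULT_INITIAL_VECTOR,
    EquilibriumResult,
    ProjectionContext,
    solve_equilibrium,
)
from .rates import STAGES, STATES, DensityDependenceSpec

__all__ = ["UrbanCatPopulationModel", "UrbanCatPopulationResultsWarning",
           "UrbanCatPopulationResults", "NonConvergenceError"]


class NonConvergenceError(RuntimeError):
    """Raised by ``fit(raise_on_nonconvergence=True)`` when the
    projection fails to settle; carries the diagnosed result."""

    def __init__(self, result: EquilibriumResult):
        self.result = result
        super().__init__(
            f"equilibrium not reached after {result.iterations} iterations "
            f"(diagnostic: {result.diagnostic}, final step change "
            f"{result.step_change:.3e})"
        )


class UrbanCatPopulationModel:
    """Multistate cat population model for one urban area.

    Parameters
    ----------
    city : CityInputs
        Latitude, dwellings, urban area, and optional density /
        shelter-size overrides.
    overrides : mapping, optional
        Named overrides of any :class:`ParameterSet` field.
    density_dependence : DensityDependenceSpec, optional
        Survival variant and kitten composition rule.
    sterilization_set : {"table1", "text"}
        Which published unowned sterilization rates to use.
    """

    def __init__(
        self,
        city: CityInputs,
        overrides=None,
        density_dependence: DensityDependenceSpec | None = None,
        sterilization_set: str = "table1",
        use_derived_loss: bool = False,
        season: BreedingSeasonParams | None = None,
        offspring_sterilization: bool = True,
    ):
        self.city = city
        self.density_dependence = density_dependence or DensityDependenceSpec()
        self.sterilization_set = sterilization_set
        self.offspring_sterilization = offspring_sterilization
        self.params, self.carrying_capacities = build_parameter_set(
            city,
            overrides=overrides,
            sterilization_set=sterilization_set,
            use_derived_loss=use_derived_loss,
            season=season,
        )
        self.context = ProjectionContext.for_city(
            city,
            self.params,
            self.carrying_capacities,
            self.density_dependence,
            offspring_sterilization=offspring_sterilization,
        )

    @classmethod
    def from_config(cls, path) -> "UrbanCatPopulationModel":
        """Build a model from a YAML run configuration file."""
        from .config import load_config

        cfg = load_config(path)
        return cfg.build_model()

    def fit(
        self,
        start: np.ndarray | None = None,
        max_iter: int = 1200,
        tol: float = 1e-9,
        raise_on_nonconvergence: bool = False,
    ) -> "UrbanCatPopulationResults":
        """Solve for the density-dependent equilibrium.

        ``start`` defaults to the standard initial vector (per stage:
        100 owned, 0 shelter, 300 free-roaming, 40 feral females).
        """
        eq = solve_equilibrium(self.context, n0=start, max_iter=max_iter, tol=tol)
        if raise_on_nonconvergence and not eq.converged:
            raise NonConvergenceError(eq)
        return UrbanCatPopulationResults(self, eq)


class UrbanCatPopulationResultsWarning(UserWarning):
    pass


class UrbanCatPopulationResults:
    """Equilibrium results for a fitted city model."""

    def __init__(self, model: UrbanCatPopulationModel, equilibrium: EquilibriumResult):
        self.model = model
        self.equilibrium = equilibrium

    # -- convenience views ------------------------------------------------
    @property
    def converged(self) -> bool:
        return self.equilibrium.converged

    @property
    def params(self) -> ParameterSet:
        return self.model.params

    @property
    def carrying_capacities(self) -> CarryingCapacities:
        return self.model.carrying_capacities

    @property
    def abundance(self) -> pd.DataFrame:
        """Stage x state female abundances at equilibrium."""
        m = self.equilibrium.vector.reshape(len(STAGES), len(STATES))
        return pd.DataFrame(m, index=list(STAGES), columns=list(STATES))

    @property
    def state_totals(self) -> pd.DataFrame:
        """Per-state female and doubled (both-sex) totals plus the
        standing total (owned + free-roaming + feral)."""
        eq = self.equilibrium
        rows = {
            state: {"female": eq.female_totals[state], "both_sex": eq.both_sex_totals[state]}
            for state in STATES
        }
        rows["total"] = {"female": eq.total / 2.0, "both_sex": eq.total}
        return pd.DataFrame(rows).T

    def sterile_proportion(self, state: str) -> float:
        """Proportion of a state's female population that is sterile."""
        col = self.abundance[state]
        total = col.sum()
        if total <= 0:
            return float("nan")
        return float((col["sterile_juvenile"] + col["sterile_adult"]) / total)

    # -- elasticities ------------------------------------------------------
    def elasticities(
        self,
        method: str = "finite-difference",
        names=_sens.THETA_FIELDS,
        groups=_sens.GROUPS,
        delta: float = 1e-3,
        tol: float = 1e-11,
    ) -> pd.DataFrame:
        """Elasticities of grouped equilibrium abundance to each
        lower-level parameter (tidy frame: parameter, group, value)."""
        baseline = solve_equilibrium(
            self.model.context, n0=self.equilibrium.vector, tol=tol
        )
        if method == "finite-difference":
            return _sens.elasticity_finite_difference(
                self.model.context, baseline=baseline, names=names, groups=groups,
                delta=delta, tol=tol,
            )
        if method == "implicit":
            return _sens.elasticity_implicit(
                self.model.context, baseline=baseline, names=names, groups=groups,
                tol=tol,
            )
        raise ValueError(f"unknown method {method!r}")

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable report of the fitted equilibrium."""
        eq = self.equilibrium
        caps = self.carrying_capacities
        city = self.model.city
        lines = [
            "Urban cat population model — equilibrium summary",
            "=" * 56,
            f"City inputs: latitude {city.latitude:.2f}N, "
            f"{city.dwellings:,.0f} dwellings, {city.area_ha:,.0f} ha",
            f"Survival variant: {self.model.density_dependence.variant} "
            f"(kitten rule: {self.model.density_dependence.juvenile_rule}); "
            f"unowned sterilization set: {self.model.sterilization_set}",
            f"Litters per female per year (k): {self.params.litters_per_year:.3f}",
            f"Converged: {eq.converged} ({eq.diagnostic}) in {eq.iterations} "
            f"iterations; final step change {eq.step_change:.2e}",
            "-" * 56,
            f"{'state':<14}{'K (female)':>12}{'female':>10}{'both-sex':>12}",
        ]
        kmap = {
            "owned": caps.owned,
            "shelter": caps.shelter,
            "freeroaming": caps.freeroaming,
            "feral": caps.feral,
        }
        for state in STATES:
            lines.append(
                f"{state:<14}{kmap[state]:>12,.1f}"
                f"{eq.female_totals[state]:>10,.1f}"
                f"{eq.both_sex_totals[state]:>12,.1f}"
            )
        lines += [
            "-" * 56,
            f"Standing total (owned + free-roaming + feral): {eq.total:,.1f}",
            f"Total including shelter throughput: {eq.total_with_shelter:,.1f}",
            "Shelter row is an annual throughput (1-year residency per step).",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        eq = self.equilibrium
        return {
            "city": asdict(self.model.city),
            "variant": self.model.density_dependence.variant,
            "juvenile_rule": self.model.density_dependence.juvenile_rule,
            "sterilization_set": self.model.sterilization_set,
            "converged": eq.converged,
            "diagnostic": eq.diagnostic,
            "iterations": eq.iterations,
            "carrying_capacities": asdict(self.carrying_capacities),
            "female_totals": eq.female_totals,
            "both_sex_totals": eq.both_sex_totals,
            "total": eq.total,
            "total_with_shelter": eq.total_with_shelter,
            "vector": eq.vector.tolist(),
            "parameters": self.params.as_dict(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
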