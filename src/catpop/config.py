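"""Run configuration: YAML schema, strict validation, hashing.

The config file carries the three census inputs, optional overrides of
any model constant, the density-dependence variant, and solver /
sensitivity settings.  Unknown keys are errors at every level so a
mistyped symbol cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import CityInputs, InvalidConfiguration
from .rates import DensityDependenceSpec

__all__ = ["RunConfig", "SolverSettings", "SensitivitySettings", "load_config"]

_CITY_KEYS = {
    "latitude",
    "dwellings",
    "area_ha",
    "freeroaming_density",
    "feral_density",
    "shelter_capacity",
    "mean_length_of_stay",
    "proportion_dwellings_with_cats",
    "cats_per_dwelling",
}
_DD_KEYS = {"variant", "juvenile_rule", "table1_total_count"}
_SOLVER_KEYS = {"max_iter", "tol"}
_SENS_KEYS = {"method", "delta"}
_TOP_KEYS = _CITY_KEYS | {
    "overrides",
    "density_dependence",
    "sterilization_set",
    "use_derived_loss",
    "offspring_sterilization",
    "solver",
    "sensitivity",
    "seed",
    "output_dir",
}


@dataclass(frozen=True)
class SolverSettings:
    max_iter: int = 1200
    tol: float = 1e-9


@dataclass(frozen=True)
class SensitivitySettings:
    method: str = "finite-difference"
    delta: float = 1e-3


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one model run."""

    city: CityInputs
    overrides: dict = field(default_factory=dict)
    density_dependence: DensityDependenceSpec = field(
        default_factory=DensityDependenceSpec
    )
    sterilization_set: str = "table1"
    use_derived_loss: bool = False
    offspring_sterilization: bool = True
    solver: SolverSettings = field(default_factory=SolverSettings)
    sensitivity: SensitivitySettings = field(default_factory=SensitivitySettings)
    seed: int = 0
    output_dir: str | None = None

    def build_model(self):
        from .model import UrbanCatPopulationModel

        return UrbanCatPopulationModel(
            self.city,
            overrides=self.overrides,
            density_dependence=self.density_dependence,
            sterilization_set=self.sterilization_set,
            use_derived_loss=self.use_derived_loss,
            offspring_sterilization=self.offspring_sterilization,
        )

    def to_dict(self) -> dict:
        return {
            **dataclasses.asdict(self.city),
            "overrides": dict(self.overrides),
            "density_dependence": dataclasses.asdict(self.density_dependence),
            "sterilization_set": self.sterilization_set,
            "use_derived_loss": self.use_derived_loss,
            "offspring_sterilization": self.offspring_sterilization,
            "solver": dataclasses.asdict(self.solver),
            "sensitivity": dataclasses.asdict(self.sensitivity),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }

    def config_hash(self) -> str:
        """Stable digest identifying the resolved configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise InvalidConfiguration(
            f"unknown key(s) in {where}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidConfiguration(f"config {path} must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    for key in ("latitude", "dwellings", "area_ha"):
        if key not in raw:
            raise InvalidConfiguration(f"config is missing required key {key!r}")
    city = CityInputs(**{k: raw[k] for k in _CITY_KEYS if k in raw})

    dd_raw = raw.get("density_dependence") or {}
    _check_keys(dd_raw, _DD_KEYS, "density_dependence")
    dd = DensityDependenceSpec(**dd_raw)

    solver_raw = raw.get("solver") or {}
    _check_keys(solver_raw, _SOLVER_KEYS, "solver")
    solver = SolverSettings(**solver_raw)
    if solver.max_iter < 1 or solver.tol <= 0:
        raise InvalidConfiguration("solver requires max_iter >= 1 and tol > 0")

    sens_raw = raw.get("sensitivity") or {}
    _check_keys(sens_raw, _SENS_KEYS, "sensitivity")
    sens = SensitivitySettings(**sens_raw)
    if sens.method not in ("finite-difference", "implicit"):
        raise InvalidConfiguration(f"unknown sensitivity method {sens.method!r}")

    overrides = raw.get("overrides") or {}
    if not isinstance(overrides, dict):
        raise InvalidConfiguration("overrides must be a mapping of parameter: value")

    return RunConfig(
        city=city,
        overrides={str(k): float(v) for k, v in overrides.items()},
        density_dependence=dd,
        sterilization_set=raw.get("sterilization_set", "table1"),
        use_derived_loss=bool(raw.get("use_derived_loss", False)),
        offspring_sterilization=bool(raw.get("offspring_sterilization", True)),
        solver=solver,
        sensitivity=sens,
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
    )
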