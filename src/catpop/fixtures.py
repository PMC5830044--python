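"""Synthetic data generation and density-record handling.

Published density records for unowned cats are approximately lognormal;
the carrying-capacity density is the geometric mean (the exponentiated
mean of log densities).  The generators here produce reproducible
synthetic density records and predicted/observed comparison pairs so
every part of the package can be exercised without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DensityRecord",
    "mean_density",
    "generate_density_fixtures",
    "generate_comparison_pairs",
    "records_to_frame",
    "read_density_csv",
    "write_density_csv",
]


@dataclass(frozen=True)
class DensityRecord:
    """One published cat-density estimate (cats/ha, both sexes)."""

    density: float
    population_class: str  # "freeroaming" | "feral"
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.population_class not in ("freeroaming", "feral"):
            raise ValueError(
                f"population_class must be freeroaming or feral, "
                f"got {self.population_class!r}"
            )


def mean_density(records: Iterable[DensityRecord] | Sequence[float]) -> float:
    """Geometric-mean density: exp of the mean natural-log density."""
    vals = [r.density if isinstance(r, DensityRecord) else float(r) for r in records]
    if not vals:
        raise ValueError("need at least one density record")
    if any(v <= 0 for v in vals):
        raise ValueError("densities must be > 0")
    return math.exp(float(np.mean(np.log(vals))))


def generate_density_fixtures(
    n: int,
    log_mean: float,
    log_sd: float,
    seed: int,
    population_class: str = "freeroaming",
) -> list[DensityRecord]:
    """Reproducible lognormal density records.

    With ``log_sd = 0`` every record equals ``exp(log_mean)`` so
    :func:`mean_density` recovers the input exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.normal(log_mean, log_sd, size=n))
    return [
        DensityRecord(
            density=float(d),
            population_class=population_class,
            source=f"synthetic-{seed}-{i}",
        )
        for i, d in enumerate(draws)
    ]


def generate_comparison_pairs(
    n: int,
    seed: int,
    sigma: float = 0.0,
    slope: float = 1.0,
    intercept: float = 0.0,
    predicted_range: tuple[float, float] = (1_000.0, 50_000.0),
) -> pd.DataFrame:
    """Synthetic (predicted, observed) city pairs around a line.

    ``observed = intercept + slope * predicted + Normal(0, sigma)``;
    defaults generate exact 1:1 data for regression sanity checks.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    rng = np.random.default_rng(seed)
    predicted = rng.uniform(*predicted_range, size=n)
    observed = intercept + slope * predicted + rng.normal(0.0, sigma, size=n)
    return pd.DataFrame(
        {
            "city": [f"city-{i}" for i in range(n)],
            "predicted": predicted,
            "observed": observed,
        }
    )


def records_to_frame(records: Iterable[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "density_cats_per_ha": [r.density for r in records],
            "class": [r.population_class for r in records],
            "source": [r.source for r in records],
        }
    )


def write_density_csv(records: Iterable[DensityRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_density_csv(path: str | Path) -> list[DensityRecord]:
    frame = pd.read_csv(path)
    required = {"density_cats_per_ha", "class", "source"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing column(s) in density CSV: {sorted(missing)}")
    return [
        DensityRecord(
            density=float(d), population_class=str(c), source=str(s)
        )
        for d, c, s in zip(
            frame["density_cats_per_ha"], frame["class"], frame["source"]
        )
    ]
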