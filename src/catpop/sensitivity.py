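"""Elasticities of equilibrium abundance to lower-level parameters.

Because the model is density dependent, the quantity of interest is the
sensitivity of the *fixed point* n*(theta) rather than of an asymptotic
growth rate.  Two routes are provided and cross-check each other:

finite-difference (default)
    Central difference of log group abundance with respect to log
    parameter, each evaluation a full re-solve of the equilibrium.
    Assumption-free but one pair of solves per parameter.

implicit
    Implicit differentiation of the fixed point n* = F(n*, theta) with
    F(n, theta) = A(n; theta) n:  dn*/dtheta = (I - J)^-1 dF/dtheta,
    where J = dF/dn at the fixed point; both Jacobians are evaluated by
    central numerical differentiation of the assembled projection.

Elasticities of a parameter whose baseline value is 0 are degenerate
(the log scaling divides by theta); those entries are reported as
absolute sensitivities and flagged in the ``scale`` column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import replace

import numpy as np
import pandas as pd

from .projection import EquilibriumResult, ProjectionContext, project, solve_equilibrium
from .rates import STATES

__all__ = [
    "GROUPS",
    "THETA_FIELDS",
    "group_mask",
    "group_abundance",
    "elasticity_finite_difference",
    "elasticity_implicit",
]

#: Reporting groups: "unowned" = free-roaming + feral; "total" = owned +
#: free-roaming + feral (the standing population; shelter throughput is
#: tracked separately).
GROUPS = ("owned", "shelter", "unowned", "total")

#: Lower-level parameters entering the perturbation analysis: survival
#: baselines, litter sizes, sterilization rates, and every transition
#: constant and density-dependence curve coefficient.
THETA_FIELDS = (
    "s0_owned",
    "s1_owned",
    "s0_shelter",
    "s1_shelter",
    "surv_max_freeroaming",
    "surv_max_feral",
    "juv_feral_intercept",
    "freq_dep_slope",
    "freq_dep_intercept",
    "litter_owned",
    "litter_freeroaming",
    "litter_feral",
    "litters_per_year",
    "juvenile_breeding_fraction",
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
    "adopt_slope",
    "adopt_intercept",
    "offstreet_decay",
    "avail_slope",
    "avail_intercept",
    "surrender_slope",
    "surrender_intercept",
)


def group_mask(group: str) -> np.ndarray:
    """Boolean mask over the 16 stage-major entries selecting a group."""
    if group in STATES:
        states = (group,)
    elif group == "unowned":
        states = ("freeroaming", "feral")
    elif group == "total":
        states = ("owned", "freeroaming", "feral")
    elif group == "all":
        states = STATES
    else:
        raise KeyError(f"unknown group {group!r}")
    cols = [STATES.index(s) for s in states]
    mask = np.zeros((4, 4), dtype=bool)
    mask[:, cols] = True
    return mask.ravel()


def group_abundance(n: np.ndarray, group: str) -> float:
    """Female abundance of a group of states at a population vector."""
    n = np.asarray(n, dtype=float)
    return float(n[group_mask(group)].sum())


def _perturbed_ctx(ctx: ProjectionContext, name: str, value: float) -> ProjectionContext:
    return dataclasses.replace(ctx, params=ctx.params.replace(**{name: value}))


def _theta_step(value: float, delta: float) -> float:
    # Relative perturbation; absolute fallback for parameters at zero.
    return delta * abs(value) if value != 0.0 else delta


def _perturbation_points(
    ctx: ProjectionContext, name: str, h: float
) -> tuple[ProjectionContext | None, ProjectionContext | None, float]:
    """(hi, lo, denominator) for a difference quotient in parameter ``name``.

    Central where both perturbed parameter sets are valid; one-sided at a
    constraint boundary (e.g. a probability at exactly 1), where the
    invalid side is replaced by the baseline (returned as None).
    """
    theta = getattr(ctx.params, name)
    hi = lo = None
    try:
        hi = _perturbed_ctx(ctx, name, theta + h)
    except Exception:
        pass
    try:
        lo = _perturbed_ctx(ctx, name, theta - h)
    except Exception:
        pass
    if hi is None and lo is None:
        raise ValueError(f"cannot perturb parameter {name} at value {theta}")
    denom = 2.0 * h if (hi is not None and lo is not None) else h
    return hi, lo, denom


def elasticity_finite_difference(
    ctx: ProjectionContext,
    baseline: EquilibriumResult | None = None,
    names: tuple[str, ...] = THETA_FIELDS,
    groups: tuple[str, ...] = GROUPS,
    delta: float = 1e-3,
    max_iter: int = 1200,
    tol: float = 1e-11,
) -> pd.DataFrame:
    """Re-solve elasticities by central differences.

    Returns a tidy frame with one row per (parameter, group).  Rows for
    a perturbed run that failed to converge carry NaN, never zero.
    """
    if not 0.0 < delta <= 0.05:
        raise ValueError("delta must be in (0, 0.05]")
    if baseline is None:
        baseline = solve_equilibrium(ctx, max_iter=max_iter, tol=tol)
    if not baseline.converged:
        raise RuntimeError("baseline equilibrium did not converge")
    n_star = baseline.vector
    rows = []
    for name in names:
        theta = getattr(ctx.params, name)
        h = _theta_step(theta, delta)
        ctx_hi, ctx_lo, denom = _perturbation_points(ctx, name, h)
        res_hi = baseline if ctx_hi is None else solve_equilibrium(
            ctx_hi, n0=n_star, max_iter=max_iter, tol=tol
        )
        res_lo = baseline if ctx_lo is None else solve_equilibrium(
            ctx_lo, n0=n_star, max_iter=max_iter, tol=tol
        )
        ok = res_hi.converged and res_lo.converged
        for group in groups:
            n_g = group_abundance(n_star, group)
            if not ok:
                value, scale = float("nan"), "missing"
            else:
                dn = (
                    group_abundance(res_hi.vector, group)
                    - group_abundance(res_lo.vector, group)
                ) / denom
                if n_g == 0.0:
                    value, scale = 0.0, "elasticity"
                elif theta == 0.0:
                    value, scale = dn / n_g, "absolute"
                else:
                    value, scale = dn * theta / n_g, "elasticity"
            rows.append(
                {
                    "parameter": name,
                    "group": group,
                    "value": value,
                    "scale": scale,
                    "method": "finite-difference",
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows)


def _state_jacobian(ctx: ProjectionContext, n_star: np.ndarray) -> np.ndarray:
    """J = d[A(n) n]/dn at the fixed point, by central differences."""
    scale = max(float(np.max(np.abs(n_star))), 1.0)
    jac = np.zeros((16, 16))
    for j in range(16):
        h = 1e-6 * max(abs(n_star[j]), 1e-3 * scale)
        hi = n_star.copy()
        lo = n_star.copy()
        hi[j] += h
        lo[j] = max(lo[j] - h, 0.0)
        jac[:, j] = (project(ctx, hi) - project(ctx, lo)) / (hi[j] - lo[j])
    return jac


def elasticity_implicit(
    ctx: ProjectionContext,
    baseline: EquilibriumResult | None = None,
    names: tuple[str, ...] = THETA_FIELDS,
    groups: tuple[str, ...] = GROUPS,
    max_iter: int = 1200,
    tol: float = 1e-11,
) -> pd.DataFrame:
    """Implicit-differentiation elasticities at the fixed point."""
    if baseline is None:
        baseline = solve_equilibrium(ctx, max_iter=max_iter, tol=tol)
    if not baseline.converged:
        raise RuntimeError("baseline equilibrium did not converge")
    n_star = baseline.vector
    jac = _state_jacobian(ctx, n_star)
    lhs = np.eye(16) - jac
    cond = np.linalg.cond(lhs)
    if not np.isfinite(cond) or cond > 1e12:
        rho = float(np.max(np.abs(np.linalg.eigvals(jac))))
        raise np.linalg.LinAlgError(
            f"(I - J) numerically singular (cond {cond:.2e}, spectral radius "
            f"{rho:.6f}); use the finite-difference method"
        )
    rows = []
    for name in names:
        theta = getattr(ctx.params, name)
        h = _theta_step(theta, 1e-6)
        ctx_hi, ctx_lo, denom = _perturbation_points(ctx, name, h)
        # At the fixed point F(n*, theta) = n*, so the baseline side of a
        # one-sided difference is n* itself.
        f_hi = n_star if ctx_hi is None else project(ctx_hi, n_star)
        f_lo = n_star if ctx_lo is None else project(ctx_lo, n_star)
        dn_dtheta = np.linalg.solve(lhs, (f_hi - f_lo) / denom)
        for group in groups:
            n_g = group_abundance(n_star, group)
            dn = float(dn_dtheta[group_mask(group)].sum())
            if n_g == 0.0:
                value, scale = 0.0, "elasticity"
            elif theta == 0.0:
                value, scale = dn / n_g, "absolute"
            else:
                value, scale = dn * theta / n_g, "elasticity"
            rows.append(
                {
                    "parameter": name,
                    "group": group,
                    "value": value,
                    "scale": scale,
                    "method": "implicit",
                    "delta": float("nan"),
                }
            )
    return pd.DataFrame(rows)
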