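"""Vec-permutation projection matrix and equilibrium solver.

The female population is a 16-entry vector in stage-major order (4 life
stages x 4 ownership states).  Each annual step applies demography
within every state (a 4x4 block per state, block-diagonal in the
state-major ordering) followed by transitions among states (a 4x4 block
per stage, block-diagonal in the stage-major ordering); the commutation
(vec-permutation) matrix shuttles the vector between the two orderings
so the full projection is a single 16x16 matrix product
``A = M P^T B P`` (for equal stage and state counts the commutation
matrix is symmetric, so this coincides with the conventional
``M K B K^T`` form).

Density-dependent rates are evaluated at the start-of-step vector, so
the map ``n -> A(n) n`` is iterated to a fixed point to obtain the
deterministic equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import CarryingCapacities, CityInputs, InvalidConfiguration, ParameterSet
from .rates import (
    STAGES,
    STATES,
    DensityDependenceSpec,
    PopulationSnapshot,
    adult_unowned_survival,
    juvenile_feral_survival,
    juvenile_freeroaming_survival,
    offstreet_adoption_rate,
    shelter_adoption_rate,
    surrender_rate,
)

__all__ = [
    "DEFAULT_INITIAL_VECTOR",
    "ProjectionContext",
    "EquilibriumResult",
    "vec_permutation_matrix",
    "build_demography_block",
    "build_transition_block",
    "demographic_rates",
    "transition_rates",
    "assemble_projection",
    "project",
    "solve_equilibrium",
]

N_STAGES = len(STAGES)
N_STATES = len(STATES)

#: Published starting abundances (females): per stage, 100 owned,
#: 0 shelter, 300 free-roaming, 40 feral.
DEFAULT_INITIAL_VECTOR = np.tile([100.0, 0.0, 300.0, 40.0], N_STAGES)


def vec_permutation_matrix(s: int, r: int) -> np.ndarray:
    """Commutation matrix mapping a stage-major vector to state-major.

    For a population classified by ``s`` stages and ``r`` states, the
    returned 0/1 matrix ``P`` satisfies ``P @ stage_major = state_major``
    and ``P @ P.T = I``.  For ``s == r`` it is symmetric.
    """
    if s < 1 or r < 1:
        raise InvalidConfiguration("s and r must be >= 1")
    p = np.zeros((s * r, s * r))
    for j in range(s):  # stage
        for i in range(r):  # state
            p[i * s + j, j * r + i] = 1.0
    return p


def build_demography_block(
    s0: float,
    s1: float,
    f0: float,
    f1: float,
    n0: float,
    n1: float,
    offspring_sterilization: bool = True,
) -> np.ndarray:
    """4x4 within-state demography block over the stages
    (intact juvenile, intact adult, sterile juvenile, sterile adult).

    Surviving juveniles mature, intact survivors are sterilized with
    their stage's probability ``n``, and reproduction adds new kittens
    split between the intact and sterile kitten stages.  Column sums
    equal ``s0 (1 + f0)``, ``s1 (1 + f1)``, ``s0``, ``s1``.

    With ``offspring_sterilization`` (default) the kitten cohort is
    split by the *kitten* sterilization rate ``n0`` — kittens are
    sterilized within their first year regardless of the dam's stage.
    This is the reading under which owned-cat dynamics are regulated
    (intrinsic growth below 1, equilibrium sustained by adoption
    inflows).  Setting it False splits each stage's offspring by the
    *parent* stage's sterilization rate instead; with the default owned
    rates (n1 = 0.1) that form has intrinsic growth above 1 for any
    breeding-season length and admits no equilibrium, so it is provided
    for comparison only.
    """
    na = n0 if offspring_sterilization else n1
    b = np.array(
        [
            [s0 * f0 * (1 - n0), s1 * f1 * (1 - na), 0.0, 0.0],
            [s0 * (1 - n0), s1 * (1 - n1), 0.0, 0.0],
            [s0 * f0 * n0, s1 * f1 * na, 0.0, 0.0],
            [s0 * n0, s1 * n1, s0, s1],
        ]
    )
    if np.any(b < 0):
        raise InvalidConfiguration("negative demography entry: rates mis-specified")
    return b


@dataclass(frozen=True)
class TransitionRates:
    """Scalar transition probabilities feeding one stage's 4x4 block."""

    relinquishment: float  # r: owned -> shelter
    loss_abandonment: float  # l + a: owned -> free-roaming
    adoption: float  # d: shelter -> owned (density dependent)
    recovery: float  # c: shelter -> owned (stage dependent)
    offstreet_adoption: float  # fa: free-roaming -> owned (density dependent)
    surrender: float  # su: free-roaming -> shelter (density dependent)
    kitten_feral: float  # ff: free-roaming -> feral (juvenile stages only)
    feral_surrender: float  # fs: feral -> shelter


def build_transition_block(tr: TransitionRates) -> np.ndarray:
    """4x4 among-state transition block (columns: from owned, shelter,
    free-roaming, feral; each column sums to exactly 1).

    Outflows from a state are treated as competing risks: if the sum of
    a column's outflow probabilities exceeds 1 (e.g. near-certain
    adoption plus return-to-owner when the owned population is far
    below carrying capacity), the outflows are rescaled proportionally
    so the column remains stochastic.  Individually invalid rates
    (outside [0, 1]) raise.
    """
    for name, v in [
        ("relinquishment", tr.relinquishment),
        ("loss_abandonment", tr.loss_abandonment),
        ("adoption", tr.adoption),
        ("recovery", tr.recovery),
        ("offstreet_adoption", tr.offstreet_adoption),
        ("surrender", tr.surrender),
        ("kitten_feral", tr.kitten_feral),
        ("feral_surrender", tr.feral_surrender),
    ]:
        if not 0.0 <= v <= 1.0:
            raise InvalidConfiguration(f"transition rate {name} = {v} outside [0, 1]")

    def _column(outflows: list[float], stay_row: int) -> np.ndarray:
        total = sum(outflows)
        if total > 1.0:
            outflows = [v / total for v in outflows]
            total = 1.0
        col = np.array(outflows[:stay_row] + [1.0 - total] + outflows[stay_row:])
        return col

    m = np.column_stack(
        [
            _column([tr.relinquishment, tr.loss_abandonment, 0.0], 0),
            _column([tr.adoption + tr.recovery, 0.0, 0.0], 1),
            _column(
                [tr.offstreet_adoption, tr.surrender, tr.kitten_feral], 2
            ),
            _column([0.0, tr.feral_surrender, 0.0], 3),
        ]
    )
    return m


@dataclass(frozen=True)
class ProjectionContext:
    """Everything needed to evaluate the projection at a population state."""

    params: ParameterSet
    caps: CarryingCapacities
    dd: DensityDependenceSpec = field(default_factory=DensityDependenceSpec)
    area_ha: float | None = None
    offspring_sterilization: bool = True

    @classmethod
    def for_city(
        cls,
        city: CityInputs,
        params: ParameterSet,
        caps: CarryingCapacities,
        dd: DensityDependenceSpec | None = None,
        offspring_sterilization: bool = True,
    ) -> "ProjectionContext":
        return cls(params=params, caps=caps, dd=dd or DensityDependenceSpec(),
                   area_ha=city.area_ha,
                   offspring_sterilization=offspring_sterilization)


def demographic_rates(
    ctx: ProjectionContext, snap: PopulationSnapshot
) -> dict[str, tuple[float, float]]:
    """Per-state (s0, s1) annual survival at the current population state."""
    p, caps, dd = ctx.params, ctx.caps, ctx.dd
    s1_free = adult_unowned_survival(
        snap.freeroaming,
        caps.freeroaming,
        dd,
        "freeroaming",
        intercept=p.surv_max_freeroaming,
        area_ha=ctx.area_ha,
    )
    s0_free = juvenile_freeroaming_survival(
        snap.proportion_intact_freeroaming,
        s1_free,
        rule=dd.juvenile_rule,
        slope=p.freq_dep_slope,
        intercept=p.freq_dep_intercept,
    )
    s1_feral = adult_unowned_survival(
        snap.feral,
        caps.feral,
        dd,
        "feral",
        intercept=p.surv_max_feral,
        area_ha=ctx.area_ha,
    )
    s0_feral = juvenile_feral_survival(
        snap.feral,
        caps.feral,
        dd,
        adult_annual=s1_feral,
        rule=dd.juvenile_rule,
        intercept=p.juv_feral_intercept,
        adult_intercept=p.surv_max_feral,
        area_ha=ctx.area_ha,
    )
    return {
        "owned": (p.s0_owned, p.s1_owned),
        "shelter": (p.s0_shelter, p.s1_shelter),
        "freeroaming": (s0_free, s1_free),
        "feral": (s0_feral, s1_feral),
    }


def transition_rates(
    ctx: ProjectionContext, snap: PopulationSnapshot, stage: str
) -> TransitionRates:
    """Stage-specific transition probabilities at the current state.

    Return-to-owner uses the intact rate for intact stages and the
    sterile rate otherwise; kittens of free-roaming cats become feral
    only in the juvenile stages.
    """
    p, caps = ctx.params, ctx.caps
    d = shelter_adoption_rate(snap.owned, caps.owned, p.adopt_slope, p.adopt_intercept)
    fa = offstreet_adoption_rate(
        snap.owned,
        caps.owned,
        snap.freeroaming,
        caps.freeroaming,
        decay=p.offstreet_decay,
        avail_slope=p.avail_slope,
        avail_intercept=p.avail_intercept,
    )
    su = surrender_rate(
        snap.freeroaming,
        caps.freeroaming,
        slope=p.surrender_slope,
        intercept=p.surrender_intercept,
        avail_slope=p.avail_slope,
        avail_intercept=p.avail_intercept,
    )
    intact = stage in ("intact_juvenile", "intact_adult")
    juvenile = stage in ("intact_juvenile", "sterile_juvenile")
    return TransitionRates(
        relinquishment=p.relinquishment,
        loss_abandonment=p.loss + p.abandonment,
        adoption=d,
        recovery=p.recovery_intact if intact else p.recovery_sterile,
        offstreet_adoption=fa,
        surrender=su,
        kitten_feral=p.kitten_feral if juvenile else 0.0,
        feral_surrender=p.feral_surrender,
    )


def assemble_projection(ctx: ProjectionContext, n: np.ndarray) -> np.ndarray:
    """16x16 annual projection matrix ``A = M P^T B P`` evaluated at
    the population vector ``n`` (demography first, then transitions)."""
    snap = PopulationSnapshot.from_vector(n)
    surv = demographic_rates(ctx, snap)
    b_blocks = []
    for state in STATES:
        s0, s1 = surv[state]
        f0, f1 = ctx.params.fecundity(state)
        n0, n1 = ctx.params.sterilization(state)
        b_blocks.append(
            build_demography_block(
                s0, s1, f0, f1, n0, n1,
                offspring_sterilization=ctx.offspring_sterilization,
            )
        )
    m_blocks = [
        build_transition_block(transition_rates(ctx, snap, stage)) for stage in STAGES
    ]
    bmat = np.zeros((16, 16))
    for i, blk in enumerate(b_blocks):
        bmat[4 * i : 4 * i + 4, 4 * i : 4 * i + 4] = blk
    mmat = np.zeros((16, 16))
    for j, blk in enumerate(m_blocks):
        mmat[4 * j : 4 * j + 4, 4 * j : 4 * j + 4] = blk
    p = vec_permutation_matrix(N_STAGES, N_STATES)
    return mmat @ p.T @ bmat @ p


def project(ctx: ProjectionContext, n: np.ndarray) -> np.ndarray:
    """One annual step: evaluate all density-dependent rates at ``n``
    and return ``A(n) n``."""
    n = np.asarray(n, dtype=float)
    out = assemble_projection(ctx, n) @ n
    if not np.all(np.isfinite(out)):
        snap = PopulationSnapshot.from_vector(np.clip(n, 0, None))
        raise FloatingPointError(
            f"non-finite projection result {out} at snapshot {snap}"
        )
    return out


@dataclass(frozen=True)
class EquilibriumResult:
    """Converged (or diagnosed non-converged) population state."""

    vector: np.ndarray  # 16 female counts, stage-major
    iterations: int
    converged: bool
    tol: float
    diagnostic: str  # "converged" | "oscillatory" | "divergent" | "slow"
    step_change: float  # final max relative step change

    @property
    def female_totals(self) -> dict[str, float]:
        m = self.vector.reshape(N_STAGES, N_STATES)
        return {state: float(m[:, i].sum()) for i, state in enumerate(STATES)}

    @property
    def both_sex_totals(self) -> dict[str, float]:
        """Doubled abundances under the 1:1 sex-ratio assumption; the
        shelter entry is an annual throughput (one-year residency)."""
        return {k: 2.0 * v for k, v in self.female_totals.items()}

    @property
    def total(self) -> float:
        """Both-sex owned + free-roaming + feral standing population
        (shelter throughput reported separately)."""
        t = self.both_sex_totals
        return t["owned"] + t["freeroaming"] + t["feral"]

    @property
    def total_with_shelter(self) -> float:
        return self.total + self.both_sex_totals["shelter"]


def _relative_step(n_new: np.ndarray, n_old: np.ndarray) -> float:
    scale = np.max(np.abs(n_old))
    if scale == 0.0:
        return float(np.max(np.abs(n_new)))
    return float(np.max(np.abs(n_new - n_old)) / scale)


def solve_equilibrium(
    ctx: ProjectionContext,
    n0: np.ndarray | None = None,
    max_iter: int = 1200,
    tol: float = 1e-9,
    tail: int = 50,
) -> EquilibriumResult:
    """Iterate the density-dependent projection to a steady state.

    Stops when the max relative step change falls below ``tol`` (default
    1e-9, stabilizing reported abundances well below a hundredth of a
    cat), or after ``max_iter`` years (published cap: 1200).  A run that
    hits the cap is classified from its last ``tail`` steps as
    oscillatory (a persistent cycle), divergent (growing steps), or slow
    (contracting but unconverged); a period-2 cycle detected mid-run
    ends the iteration early with the oscillatory diagnostic.  The
    result is never flagged converged unless the criterion was met.
    """
    if max_iter < 1:
        raise InvalidConfiguration("max_iter must be >= 1")
    if tol <= 0:
        raise InvalidConfiguration("tol must be > 0")
    n = np.asarray(
        DEFAULT_INITIAL_VECTOR if n0 is None else n0, dtype=float
    ).copy()
    if n.shape != (16,) or np.any(n < 0):
        raise InvalidConfiguration("n0 must be 16 nonnegative female counts")
    prev = n.copy()
    prev2 = None
    steps: list[float] = []
    # An urban cat population many orders of magnitude above any carrying
    # capacity can only be unbounded growth; bail out before overflow.
    blowup = 1e12
    for it in range(1, max_iter + 1):
        n = project(ctx, prev)
        if np.max(n) > blowup:
            return EquilibriumResult(
                vector=n,
                iterations=it,
                converged=False,
                tol=tol,
                diagnostic="divergent",
                step_change=_relative_step(n, prev),
            )
        step = _relative_step(n, prev)
        steps.append(step)
        # Near the fixed point the iteration contracts geometrically with
        # ratio r, so the remaining distance is about step * r / (1 - r).
        # Requiring step < tol * (1 - r) bounds that distance by ~tol (and
        # implies the plain step < tol criterion).
        ratio = step / steps[-2] if len(steps) > 1 and steps[-2] > 0 else 0.5
        contraction = min(max(ratio, 0.0), 0.999)
        if step < tol * (1.0 - contraction):
            return EquilibriumResult(
                vector=n,
                iterations=it,
                converged=True,
                tol=tol,
                diagnostic="converged",
                step_change=step,
            )
        # Early period-2 cycle detection: state repeats every other step
        # while successive steps stay large.
        if prev2 is not None and it > 10:
            if _relative_step(n, prev2) < tol and step > 100 * tol:
                return EquilibriumResult(
                    vector=n,
                    iterations=it,
                    converged=False,
                    tol=tol,
                    diagnostic="oscillatory",
                    step_change=step,
                )
        prev2 = prev
        prev = n
    recent = np.array(steps[-tail:])
    if len(recent) >= 4 and recent[-1] > 2.0 * recent[0]:
        diag = "divergent"
    elif len(recent) >= 4 and np.median(np.abs(np.diff(recent))) < 0.5 * np.median(
        recent
    ) and recent[-1] > 0.5 * recent[0]:
        diag = "oscillatory"
    else:
        diag = "slow"
    return EquilibriumResult(
        vector=n,
        iterations=max_iter,
        converged=False,
        tol=tol,
        diagnostic=diag,
        step_change=steps[-1],
    )
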