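# Methods

## Model structure

`catpop` projects the female cat population of an urban area as a
16-class vector: four life stages (intact juvenile, intact adult,
sterile juvenile, sterile adult) crossed with four states (owned,
shelter, free-roaming, feral), in stage-major order. One time step is
one year. Each step first applies demography within each state (a 4x4
block `B_i`: survival, sterilization of survivors, and reproduction)
and then transitions among states (a 4x4 block `M_j` per stage whose
columns are probability distributions over destination states). The
commutation (vec-permutation) matrix `P`, which maps the stage-major
vector to state-major order, lets both processes remain block-diagonal
in the single projection matrix `A = M Pᵀ B P`. For equal numbers of
stages and states (4 and 4 here) `P` is symmetric, so this coincides
with the conventional `M K B Kᵀ` form of periodic vec-permutation
models.

Assumptions inherited from the modeled system: a birth-pulse annual
census; females only, with both-sex abundances reported by doubling
under a 1:1 sex ratio; deterministic dynamics with density dependence
standing in for environmental regulation; transitions occur after
demography and involve no additional mortality; shelter residency is
one census interval, so the equilibrium shelter abundance is an annual
throughput, not a standing population.

### The demography block and sterilization timing

The within-state block applies survival (`s0` juveniles, `s1` adults),
sterilization of the intact survivors (`n0`, `n1`), and reproduction
(`f0`, `f1` female kittens per female per year). A genuine modeling
choice arises for the offspring cohort: whether newborn kittens are
split between the intact and sterile kitten classes by the *kitten*
sterilization rate `n0` (kittens are sterilized within their first
year) or by their *dam's* stage-specific rate. `catpop` defaults to the
kitten-rate split. The alternative (dam's rate, available via
`offspring_sterilization=False`) leaves 90% of adult-born kittens
intact under the default owned rates (`n1 = 0.1`), which gives the
owned subsystem an intrinsic annual growth rate of about 1.07 that no
mechanism in the model regulates — every city then grows without bound
and no equilibrium exists. Under the kitten-rate split the owned
subsystem is subcritical (growth ≈ 0.85 after transitions) and is
sustained at equilibrium by adoption and off-street-adoption inflows,
which is the only reading under which the published equilibria of this
model family can exist at all. Column sums of the block equal
`s0(1+f0), s1(1+f1), s0, s1` under either reading.

### Transition blocks and competing risks

Each stage's transition matrix has columns (from owned, shelter,
free-roaming, feral):

- owned: remain `1-(r+l+a)`; relinquishment `r = 0.012` to shelter;
  loss `l = 0.0049` plus abandonment `a = 0.05` to free-roaming.
- shelter: adoption `d` (density-dependent) plus return-to-owner `c`
  to owned; remainder stays.
- free-roaming: off-street adoption `fa` and surrender `su` (both
  density-dependent); kittens becoming feral `ff = 0.05` (juvenile
  stages only); remainder stays.
- feral: surrender `fs = 0.0001` to shelter; remainder stays.

Return-to-owner is stage-specific: `c = 0.0385` for intact cats,
`0.0877` for sterile cats (sterile cats are likelier to carry
identification and be reclaimed).

When the owned population is far below its carrying capacity the
adoption logistic approaches 1 and `d + c` exceeds 1. Simultaneous
outflows are therefore treated as competing risks: any column whose
outflow probabilities sum past 1 is rescaled proportionally so it
remains stochastic. This occurs on the standard initial trajectory
(owned cats start at 400 females against carrying capacities in the
tens of thousands) and is a property of the published rate functions,
not an error state; individually invalid rates (outside [0, 1]) still
raise.

### Derived constants

- Annual loss probability: the cumulative-loss model `L = a ln(t+1)`
  calibrated to 15% over 5 years gives `a = 0.15/ln 6` and an annual
  (t = 1) loss of 0.0580. The natural logarithm is used; base 10 gives
  the same value to three decimals. Only the fraction of lost cats
  returned via shelters (6/69) enters the model; the derivation chain
  yields 0.0050, the published constant 0.0049 is the default (both are
  available).
- Return-to-owner: `c_sterile = 0.385·0.19 + 0.018·0.81 = 0.0877`
  combining return rates with/without identification; intact cats at
  relative odds `0.25/0.57 = 0.4386` of that.
- Off-street adoption decay: `e^{-a} = 0.3` at carrying capacity gives
  `a = 1.20397`.

## City parameterization

Three inputs parameterize a city: latitude (drives reproduction),
dwellings (owned carrying capacity `K_o = 0.377 x 1.85 x h / 2`,
Canadian ownership statistics; presets for other countries can be set
via `CityInputs`), and urban area in hectares (unowned carrying
capacities `K = density x area / 2`). Default unowned densities are the
geometric means of published density records: 0.4711 cats/ha
(free-roaming) and 0.0791 cats/ha (feral), both sexes. Shelter
throughput capacity is `capacity x (365 / mean stay) / 2` with defaults
187 spaces and a 30-day stay.

Breeding season length follows a 4-parameter logistic in latitude
(`a = 365` fixed so equatorial breeding is year-round, `b = 170.35`,
slope `c = 0.1351`/degree, inflection `d = 31.84°`); litters per year
is season length / 149 days (65 gestation + 84 weaning). Kittens breed
in the post-pubertal fraction of their first year,
`(365 - 212)/365 = 0.419`, applied to adult fecundity. Litter sizes
(3.8 owned, 3.6 free-roaming, 3.5 feral kittens, halved to females) and
all sterilization and transition constants are overridable from the
YAML config; unknown keys and out-of-range probabilities are errors.

## Density-dependent survival variants

Published parameterizations of unowned survival conflict; three
families are implemented and selectable (`DensityDependenceSpec`):

- `calibrated` (default): `a e^{-b N/K}` with `b = ln(a/0.5)` solved
  from the one explicitly stated calibration — adult survival 0.5 at
  carrying capacity. Intercepts `a` are 0.82 (free-roaming adults),
  0.65 (feral adults), 0.25 (feral kittens, six-month).
- `eq14_16`: composite forms `0.82 e^{-0.476 e^{0.0482 N/K}}` and
  `0.65 e^{-3.812 e^{-2.676 N/K}}`. The feral form *increases* with
  density (Allee-like); implemented verbatim, but from the standard
  initial conditions the feral class crashes and the network decays to
  extinction, so this variant never reaches a positive equilibrium.
- `table1`: density-unit decays `0.82 e^{-0.4757 N/area}` and
  `0.65 e^{-10.07 N/area}` with N interpreted as the female count
  (a flag selects the doubled count; the unit is ambiguous in the
  source material).

Free-roaming kitten survival is frequency-dependent:
`-0.587 p + 0.907` over six months, where `p` is the intact fraction of
adult free-roaming cats (hormone-mediated aggression in intact
colonies). Annual kitten survival composes the six-month rate with the
adult rate for the second half-year — by default with
`sqrt(adult annual)` (the stated half-year adult rate), optionally with
the full annual adult survival (the published table's form). All rates
are clamped to [0, 1] after evaluation.

## Equilibrium solver

Fixed-point iteration of `n -> A(n) n` from the standard initial vector
(per stage: 100 owned, 0 shelter, 300 free-roaming, 40 feral females),
capped at 1200 iterations. Density-dependent rates are evaluated at the
start-of-step vector. The stopping rule bounds the *distance to the
fixed point*, not just the step: with `r` the current step-ratio
estimate of the contraction rate, iteration stops when the max relative
step change is below `tol x (1 - r)` (default `tol = 1e-9`, keeping
reported abundances stable to well under 0.01 cats, and implying the
plain step-below-tol criterion). Runs that hit the cap are classified
from their step history as `divergent` (growing steps; also triggered
early if abundance exceeds 10^12), `oscillatory` (a persistent cycle —
a period-2 repeat within tolerance ends the run early), or `slow`.
Non-convergence is always an explicit diagnostic, never an exception or
a silent success; the CLI exits with a distinct status code. The
bundled `lowlat.yaml` demonstrates the failure mode: a near-equatorial
city (latitude 21.3, near year-round breeding) under the
dam's-rate demography form grows without bound and is diagnosed
`divergent` within ~90 iterations.

## Sensitivity analysis

Elasticities `(θ/N_g) ∂N_g/∂θ` of grouped equilibrium female abundance
(owned, shelter, unowned = free-roaming + feral, total = owned +
free-roaming + feral) with respect to every lower-level parameter:
survival baselines, litter sizes, sterilization rates, all transition
constants and density-dependence curve coefficients (36 parameters).
Two routes:

- finite-difference (default): central differences of the re-solved
  equilibrium at relative perturbation `δ = 1e-3` (re-solves use
  `tol = 1e-11`); assumption-free.
- implicit (fast path): differentiate the fixed point
  `n* = A(n*, θ) n*`, solving `(I - J) dn*/dθ = ∂(A n)/∂θ` with `J` the
  numerical Jacobian of the one-step map at `n*`; errors if `(I - J)`
  is near-singular (spectral radius of `J` near 1).

Both are exposed; on the case-study configuration they agree to better
than 0.03% on every entry exceeding 1e-4. Parameters at a constraint
boundary (e.g. shelter sterilization = 1) use one-sided differences; a
parameter whose baseline value is 0 is reported as an absolute
sensitivity and flagged in the `scale` column, since the elasticity
scaling is degenerate there. Elasticities are computed on female
abundances; the 1:1 both-sex doubling cancels in the log-derivative.

## Validation statistics

Predicted-vs-observed model fit uses ordinary least squares of observed
on predicted (direction documented; the reverse is a user choice) with
t tests of intercept = 0 and slope = 1 on n - 2 df. Exact-fit data
(zero residual variance) is flagged `perfect_fit` rather than reporting
0/0 statistics. Binomial confidence intervals for observed sterile
proportions default to Clopper-Pearson (exact, conservative; boundary
endpoints are exactly 0 and 1); Wilson is available by flag. The
external city datasets behind the original fit assessments are not
bundled; the statistics run on user-supplied or synthetic pairs.

## Synthetic data

`catpop.fixtures` generates the two external inputs the tools consume:
lognormal density records (emulating compiled literature density
estimates, which are approximately lognormal; with `log_sd = 0` the
geometric mean recovers the input exactly) and predicted/observed
comparison pairs around a configurable line. These reproduce the
*shape* of real inputs — they do not carry the sampling biases,
study-area heterogeneity, or expert-judgment error of real density
compilations, so tests passing on them show the machinery is correct,
not that real-city predictions are accurate.

## Case-study reproduction status

With the printed Guelph inputs (latitude 43.55, 52,620 dwellings,
7,885 ha, adjusted unowned densities 0.787 / 0.246 cats/ha), the sweep
over all 12 printed variant combinations is scored against the
published equilibrium abundances by mean absolute relative error. The
best match (table1 survival, table1 sterilization, sqrt kitten
composition) reproduces owned (-1.1%), free-roaming (+4.8%) and the
standing total (-3.1%); the feral abundance comes out ~75% low and
shelter throughput ~20% high under every combination. At the printed
fecundities and any of the printed decreasing survival curves, a feral
population near its (adjusted) carrying capacity has sub-replacement
growth, so the published feral abundance is not an equilibrium of any
printed rate family; `reproduction_report` documents this gap
explicitly. Likewise, eight of ten published directional elasticity
claims reproduce; the two that do not (owned sterilization and
relinquishment *increasing* unowned abundance) carry the opposite sign
under every regulated parameterization here, because a lower owned
population raises off-street adoption demand and drains the unowned
pool.

## Known limitations

- Deterministic only: no environmental or demographic stochasticity,
  no parameter uncertainty propagation.
- The shelter carrying capacity is computed and reported but does not
  cap intake by default, matching the equilibrium analyses this model
  family is used for.
- Transition rates assume no mortality during movement between states
  and identical transition probabilities across stages except where
  stated (return-to-owner, kittens-becoming-feral).
- Carrying capacities treat published density compilations as
  equilibrium densities; cities whose unowned populations are far from
  equilibrium will be mis-parameterized.
- The latitude-breeding relationship extrapolates poorly outside the
  latitudes of its source data; near-equatorial cities may not admit a
  stable equilibrium at all (see the failure-mode diagnostics).
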