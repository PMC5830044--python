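"""Projection assembly and the equilibrium solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catpop import (
    CityInputs,
    UrbanCatPopulationModel,
    project,
    solve_equilibrium,
    vec_permutation_matrix,
)
from catpop.casestudy import GUELPH
from catpop.params import InvalidConfiguration
from catpop.projection import (
    DEFAULT_INITIAL_VECTOR,
    TransitionRates,
    assemble_projection,
    build_demography_block,
    build_transition_block,
    demographic_rates,
    transition_rates,
)
from catpop.rates import STAGES, STATES, PopulationSnapshot

prob = st.floats(min_value=0.0, max_value=1.0)
fec = st.floats(min_value=0.0, max_value=5.0)


class TestVecPermutation:
    def test_trivial_size(self):
        assert np.array_equal(vec_permutation_matrix(1, 1), np.eye(1))

    def test_orthogonal_permutation(self):
        p = vec_permutation_matrix(4, 4)
        assert np.array_equal(p @ p.T, np.eye(16))
        assert np.array_equal(np.sort(p, axis=0)[-1], np.ones(16))
        assert p.sum() == 16  # exactly one 1 per row and column

    def test_two_by_two_reordering(self):
        # brute force: stage-major (n11, n12, n21, n22) -> state-major
        p = vec_permutation_matrix(2, 2)
        assert np.array_equal(p @ np.array([1.0, 2.0, 3.0, 4.0]),
                              np.array([1.0, 3.0, 2.0, 4.0]))

    def test_rectangular_roundtrip(self):
        p = vec_permutation_matrix(3, 5)
        assert np.array_equal(p @ p.T, np.eye(15))
        stage_major = np.arange(15.0)
        state_major = stage_major.reshape(3, 5).T.ravel()
        assert np.array_equal(p @ stage_major, state_major)


class TestDemographyBlock:
    def test_symbol_substitution(self):
        b = build_demography_block(0.5, 0.5, 0.0, 2.0, 0.0, 0.0)
        expected = np.array(
            [
                [0.0, 1.0, 0.0, 0.0],
                [0.5, 0.5, 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0],
                [0.0, 0.0, 0.5, 0.5],
            ]
        )
        assert np.allclose(b, expected)

    def test_full_sterilization_empties_intact_stages(self):
        b = build_demography_block(0.7, 0.8, 1.0, 2.0, 1.0, 1.0)
        assert np.all(b[:2] == 0.0)
        assert b[:, 0].sum() == pytest.approx(0.7 * 2.0)  # all flow is sterile

    @given(s0=prob, s1=prob, f0=fec, f1=fec, n0=prob, n1=prob)
    def test_column_sums_closed_form(self, s0, s1, f0, f1, n0, n1):
        for offspring in (True, False):
            b = build_demography_block(s0, s1, f0, f1, n0, n1, offspring)
            assert np.allclose(
                b.sum(axis=0), [s0 * (1 + f0), s1 * (1 + f1), s0, s1]
            )
            assert np.all(b >= 0)


class TestTransitionBlock:
    @staticmethod
    def _block(**kw):
        base = dict(
            relinquishment=0.0,
            loss_abandonment=0.0,
            adoption=0.0,
            recovery=0.0,
            offstreet_adoption=0.0,
            surrender=0.0,
            kitten_feral=0.0,
            feral_surrender=0.0,
        )
        base.update(kw)
        return build_transition_block(TransitionRates(**base))

    def test_no_transitions_is_identity(self):
        assert np.array_equal(self._block(), np.eye(4))

    @given(
        r=prob, la=prob, d=prob, c=prob, fa=prob, su=prob, ff=prob, fs=prob
    )
    def test_columns_always_sum_to_one(self, r, la, d, c, fa, su, ff, fs):
        m = self._block(
            relinquishment=r,
            loss_abandonment=la,
            adoption=d,
            recovery=c,
            offstreet_adoption=fa,
            surrender=su,
            kitten_feral=ff,
            feral_surrender=fs,
        )
        assert np.allclose(m.sum(axis=0), 1.0)
        assert np.all((m >= 0) & (m <= 1))

    def test_competing_outflows_rescaled_proportionally(self):
        # adoption + recovery past 1 keeps relative shares intact
        m = self._block(adoption=0.9, recovery=0.3)
        assert m[0, 1] == pytest.approx(1.0)
        assert m[1, 1] == pytest.approx(0.0)

    def test_rejects_individually_invalid_rate(self):
        with pytest.raises(InvalidConfiguration):
            self._block(adoption=1.2)

    def test_kittens_become_feral_only_from_juvenile_stages(self, guelph_model):
        snap = PopulationSnapshot.from_vector(DEFAULT_INITIAL_VECTOR)
        for stage in STAGES:
            tr = transition_rates(guelph_model.context, snap, stage)
            if stage in ("intact_juvenile", "sterile_juvenile"):
                assert tr.kitten_feral == guelph_model.params.kitten_feral
            else:
                assert tr.kitten_feral == 0.0

    def test_recovery_rate_is_stage_specific(self, guelph_model):
        snap = PopulationSnapshot.from_vector(DEFAULT_INITIAL_VECTOR)
        p = guelph_model.params
        assert transition_rates(
            guelph_model.context, snap, "intact_adult"
        ).recovery == p.recovery_intact
        assert transition_rates(
            guelph_model.context, snap, "sterile_adult"
        ).recovery == p.recovery_sterile


class TestAssembleAndProject:
    def test_projection_matches_blockwise_hand_computation(self, guelph_model):
        """Independent oracle: apply demography per state then transitions
        per stage with explicit loops instead of the assembled matrix."""
        ctx = guelph_model.context
        n = DEFAULT_INITIAL_VECTOR.copy()
        snap = PopulationSnapshot.from_vector(n)
        surv = demographic_rates(ctx, snap)
        mid = np.zeros(16)
        m = n.reshape(4, 4)  # stages x states
        for i, state in enumerate(STATES):
            s0, s1 = surv[state]
            f0, f1 = ctx.params.fecundity(state)
            n0, n1 = ctx.params.sterilization(state)
            from catpop.projection import build_demography_block

            block = build_demography_block(s0, s1, f0, f1, n0, n1)
            mid.reshape(4, 4)[:, i] = block @ m[:, i]
        out = np.zeros(16)
        for j, stage in enumerate(STAGES):
            block = build_transition_block(transition_rates(ctx, snap, stage))
            out.reshape(4, 4)[j, :] = block @ mid.reshape(4, 4)[j, :]
        assert np.allclose(project(ctx, n), out, rtol=1e-12)

    def test_matrix_is_nonnegative_with_stochastic_transition_part(
        self, guelph_model
    ):
        ctx = guelph_model.context
        a = assemble_projection(ctx, DEFAULT_INITIAL_VECTOR)
        assert np.all(a >= 0)
        # transitions conserve individuals, so the column sums of A equal
        # the demographic column sums rearranged through the permutation
        from catpop.projection import vec_permutation_matrix

        p = vec_permutation_matrix(4, 4)
        snap = PopulationSnapshot.from_vector(DEFAULT_INITIAL_VECTOR)
        surv = demographic_rates(ctx, snap)
        bmat = np.zeros((16, 16))
        for i, state in enumerate(STATES):
            s0, s1 = surv[state]
            f0, f1 = ctx.params.fecundity(state)
            n0, n1 = ctx.params.sterilization(state)
            from catpop.projection import build_demography_block

            bmat[4 * i : 4 * i + 4, 4 * i : 4 * i + 4] = build_demography_block(
                s0, s1, f0, f1, n0, n1
            )
        assert np.allclose(a.sum(axis=0), (p.T @ bmat @ p).sum(axis=0))

    def test_extinction_is_absorbing(self, guelph_model):
        assert np.allclose(project(guelph_model.context, np.zeros(16)), 0.0)

    def test_density_dependence_breaks_homogeneity(self, guelph_model):
        n = DEFAULT_INITIAL_VECTOR
        doubled = project(guelph_model.context, 2.0 * n)
        assert not np.allclose(doubled, 2.0 * project(guelph_model.context, n))


class TestSolveEquilibrium:
    def test_zero_survival_reaches_empty_equilibrium_fast(self):
        city = CityInputs(latitude=45.0, dwellings=1000, area_ha=100)
        from catpop.rates import DensityDependenceSpec

        model = UrbanCatPopulationModel(
            city,
            overrides={
                "s0_owned": 0.0,
                "s1_owned": 0.0,
                "s0_shelter": 0.0,
                "s1_shelter": 0.0,
                "surv_max_freeroaming": 0.0,
                "surv_max_feral": 0.0,
                "juv_feral_intercept": 0.0,
                "freq_dep_intercept": 0.0,
                "freq_dep_slope": 0.0,
            },
            density_dependence=DensityDependenceSpec(variant="eq14_16"),
        )
        eq = model.fit().equilibrium
        assert eq.converged
        assert eq.iterations <= 2
        assert np.allclose(eq.vector, 0.0)

    def test_fixed_point_residual_below_tolerance(self, guelph_results):
        eq = guelph_results.equilibrium
        ctx = guelph_results.model.context
        residual = project(ctx, eq.vector) - eq.vector
        assert np.max(np.abs(residual)) / np.max(np.abs(eq.vector)) < eq.tol

    def test_equilibrium_independent_of_positive_start(self, guelph_model):
        tol = 1e-9
        r1 = solve_equilibrium(guelph_model.context, n0=np.full(16, 10.0), tol=tol)
        r2 = solve_equilibrium(
            guelph_model.context,
            n0=np.tile([1000.0, 500.0, 2000.0, 100.0], 4),
            tol=tol,
        )
        assert r1.converged and r2.converged
        gap = np.max(np.abs(r1.vector - r2.vector)) / np.max(r1.vector)
        assert gap < 10 * tol

    def test_doubled_totals_and_grand_total(self, guelph_results):
        eq = guelph_results.equilibrium
        for state, female in eq.female_totals.items():
            assert eq.both_sex_totals[state] == pytest.approx(2 * female)
        assert eq.total == pytest.approx(
            sum(eq.both_sex_totals[s] for s in ("owned", "freeroaming", "feral"))
        )
        assert eq.total_with_shelter == pytest.approx(
            eq.total + eq.both_sex_totals["shelter"]
        )

    def test_unbounded_growth_is_diagnosed_not_raised(self):
        # verbatim printed demography: intrinsic growth above 1
        model = UrbanCatPopulationModel(GUELPH, offspring_sterilization=False)
        eq = model.fit().equilibrium
        assert not eq.converged
        assert eq.diagnostic == "divergent"

    def test_never_reports_unmet_criterion_as_converged(self, guelph_model):
        eq = solve_equilibrium(guelph_model.context, max_iter=5, tol=1e-9)
        assert not eq.converged
        assert eq.iterations == 5
        assert eq.diagnostic in ("slow", "oscillatory", "divergent")

    def test_solver_input_validation(self, guelph_model):
        with pytest.raises(InvalidConfiguration):
            solve_equilibrium(guelph_model.context, max_iter=0)
        with pytest.raises(InvalidConfiguration):
            solve_equilibrium(guelph_model.context, tol=0.0)
        with pytest.raises(InvalidConfiguration):
            solve_equilibrium(guelph_model.context, n0=np.full(16, -1.0))
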