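"""Density- and frequency-dependent vital rate functions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from catpop.params import InvalidConfiguration
from catpop.rates import (
    DensityDependenceSpec,
    PopulationSnapshot,
    adult_unowned_survival,
    feral_juvenile_six_month,
    freeroaming_juvenile_six_month,
    juvenile_feral_survival,
    juvenile_freeroaming_survival,
    offstreet_adoption_rate,
    shelter_adoption_rate,
    surrender_rate,
)

CAL = DensityDependenceSpec(variant="calibrated")
EQ = DensityDependenceSpec(variant="eq14_16")
T1 = DensityDependenceSpec(variant="table1")

nonneg = st.floats(min_value=0.0, max_value=1e7)
positive = st.floats(min_value=1e-3, max_value=1e6)


class TestAdultUnownedSurvival:
    def test_calibrated_hits_half_at_carrying_capacity_exactly(self):
        assert adult_unowned_survival(1000.0, 1000.0, CAL, "freeroaming") == 0.5
        assert adult_unowned_survival(500.0, 500.0, CAL, "feral") == 0.5

    def test_calibrated_intercepts(self):
        assert adult_unowned_survival(0.0, 100.0, CAL, "freeroaming") == 0.82
        assert adult_unowned_survival(0.0, 100.0, CAL, "feral") == 0.65

    def test_composite_forms_at_carrying_capacity(self):
        # the composite forms meet the 0.5-at-K constraint only approximately
        assert adult_unowned_survival(1.0, 1.0, EQ, "freeroaming") == pytest.approx(
            0.4976013, abs=1e-6
        )
        assert adult_unowned_survival(1.0, 1.0, EQ, "feral") == pytest.approx(
            0.4999770, abs=1e-6
        )

    def test_table1_uses_density_units(self):
        # decay operates on N/area, so halving the area doubles the decay
        lo = adult_unowned_survival(100.0, 50.0, T1, "freeroaming", area_ha=1000.0)
        hi = adult_unowned_survival(100.0, 50.0, T1, "freeroaming", area_ha=2000.0)
        assert lo < hi
        with pytest.raises(InvalidConfiguration):
            adult_unowned_survival(100.0, 50.0, T1, "freeroaming")

    def test_rejects_invalid_inputs(self):
        with pytest.raises(InvalidConfiguration):
            adult_unowned_survival(1.0, 0.0, CAL, "freeroaming")
        with pytest.raises(InvalidConfiguration):
            adult_unowned_survival(1.0, 1.0, CAL, "owned")

    @given(n=nonneg, k=positive)
    def test_bounded_probability(self, n, k):
        for spec in (CAL, EQ, T1):
            s = adult_unowned_survival(n, k, spec, "freeroaming", area_ha=1000.0)
            assert 0.0 <= s <= 1.0

    @given(n=st.floats(min_value=0.0, max_value=1e5), k=positive)
    def test_monotone_non_increasing_in_abundance(self, n, k):
        # holds for the decaying families; the composite feral form is
        # excluded (it increases with density as printed)
        for spec, state in ((CAL, "freeroaming"), (CAL, "feral"),
                            (EQ, "freeroaming"), (T1, "freeroaming"), (T1, "feral")):
            lo = adult_unowned_survival(n, k, spec, state, area_ha=1000.0)
            hi = adult_unowned_survival(n * 1.5 + 1.0, k, spec, state, area_ha=1000.0)
            assert hi <= lo + 1e-12

    def test_composite_feral_form_increases_with_density(self):
        assert adult_unowned_survival(2.0, 1.0, EQ, "feral") > adult_unowned_survival(
            1.0, 1.0, EQ, "feral"
        )


class TestJuvenileSurvival:
    @pytest.mark.parametrize("p, expected", [(0.0, 0.907), (1.0, 0.32)])
    def test_freeroaming_six_month_frequency_dependence(self, p, expected):
        assert freeroaming_juvenile_six_month(p) == pytest.approx(expected)

    def test_freeroaming_annual_composition(self):
        # six-month rate x sqrt(adult annual) for the second half-year
        assert juvenile_freeroaming_survival(0.5, 0.64, "sqrt_adult") == pytest.approx(
            (0.907 - 0.587 / 2) * 0.8
        )
        assert juvenile_freeroaming_survival(0.5, 0.64, "full_adult") == pytest.approx(
            (0.907 - 0.587 / 2) * 0.64
        )

    def test_feral_six_month_is_rescaled_adult_curve(self):
        # kitten intercept 0.25 scaled along the adult density response
        assert feral_juvenile_six_month(0.0, 100.0, CAL) == pytest.approx(0.25)
        assert feral_juvenile_six_month(1.0, 1.0, EQ) == pytest.approx(
            0.1922988, abs=1e-6
        )

    def test_feral_annual_composition(self):
        got = juvenile_feral_survival(
            1.0, 1.0, CAL, adult_annual=0.5, rule="full_adult"
        )
        assert got == pytest.approx(0.25 * (0.5 / 0.65) * 0.5, rel=1e-9)

    @given(p=st.floats(0.0, 1.0), adult=st.floats(0.0, 1.0))
    def test_juvenile_rates_are_probabilities(self, p, adult):
        for rule in ("sqrt_adult", "full_adult"):
            assert 0.0 <= juvenile_freeroaming_survival(p, adult, rule) <= 1.0


class TestTransitionRates:
    def test_shelter_adoption_examples(self):
        assert shelter_adoption_rate(1000.0, 1000.0) == pytest.approx(0.5)
        assert shelter_adoption_rate(0.0, 1000.0) == pytest.approx(
            0.9999938558, abs=1e-9
        )
        assert shelter_adoption_rate(2000.0, 1000.0) == pytest.approx(
            6.144174e-06, rel=1e-5
        )

    @given(n=st.floats(min_value=0.0, max_value=4e4))
    def test_shelter_adoption_decreasing(self, n):
        # above ~5e4 the logistic underflows to indistinguishable denormals
        assert shelter_adoption_rate(n + 1.0, 1000.0) < shelter_adoption_rate(
            n, 1000.0
        )

    def test_offstreet_adoption_examples(self):
        assert offstreet_adoption_rate(1.0, 1.0, 1.0, 1.0) == pytest.approx(
            0.0736018, abs=1e-6
        )
        assert offstreet_adoption_rate(1.0, 1.0, 0.0, 1.0) == pytest.approx(
            0.0020079, abs=1e-6
        )
        # owner demand vanishes as the owned population saturates
        assert offstreet_adoption_rate(1e9, 1.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_surrender_examples(self):
        assert surrender_rate(1.0, 1.0) == pytest.approx(0.0973572, abs=1e-6)
        assert surrender_rate(0.0, 1.0) == pytest.approx(0.0023934, abs=1e-6)

    @given(x=st.floats(min_value=0.0, max_value=50.0))
    def test_surrender_monotone_increasing(self, x):
        assert surrender_rate(x + 0.1, 1.0) > surrender_rate(x, 1.0)

    def test_rejects_nonpositive_carrying_capacity(self):
        for fn in (
            lambda: shelter_adoption_rate(1.0, 0.0),
            lambda: offstreet_adoption_rate(1.0, 0.0, 1.0, 1.0),
            lambda: surrender_rate(1.0, 0.0),
        ):
            with pytest.raises(InvalidConfiguration):
                fn()


class TestPopulationSnapshot:
    def test_aggregates_match_entry_sums(self):
        n = np.arange(16, dtype=float)
        snap = PopulationSnapshot.from_vector(n)
        m = n.reshape(4, 4)
        assert snap.owned == m[:, 0].sum()
        assert snap.freeroaming == m[:, 2].sum()
        assert snap.feral == m[:, 3].sum()
        assert snap.freeroaming_intact_adults == m[1, 2]
        assert snap.freeroaming_sterile_adults == m[3, 2]
        expected_p = m[1, 2] / (m[1, 2] + m[3, 2])
        assert snap.proportion_intact_freeroaming == pytest.approx(expected_p)

    def test_empty_adult_pool_counts_as_fully_sterile(self):
        snap = PopulationSnapshot.from_vector(np.zeros(16))
        assert snap.proportion_intact_freeroaming == 0.0

    def test_rejects_negative_or_misshaped_vectors(self):
        with pytest.raises(ValueError):
            PopulationSnapshot.from_vector(np.zeros(15))
        with pytest.raises(ValueError):
            PopulationSnapshot.from_vector(np.full(16, -1.0))
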