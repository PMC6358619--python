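"""Vital rates and the one-step demography contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastlife.agents import NEWBORN, MutationParams, Population
from plastlife.lifecycle import (LifeHistoryParams, clutch_size,
                                 mortality_prob, recruit, step_population)


class TestClutchSize:
    @pytest.mark.parametrize(
        "r, m, updated, kappa, expected",
        [
            (9.0, 0.0, 0, 0.4, 9.0),
            (9.0, 0.0, 1, 0.4, 5.4),                 # updating cost
            (12.0, 1.0, 0, 0.4, 10 * np.exp(-1)),    # effort capped at 10
            (4.0, 0.5, 1, 0.2, 4 * np.exp(-0.25) * 0.8),
        ],
    )
    def test_formula(self, r, m, updated, kappa, expected):
        assert clutch_size(r, m, updated, kappa=kappa) == pytest.approx(expected)

    def test_mortality_only_variant_drops_mismatch_term(self):
        assert clutch_size(6.0, 2.0, 1, kappa=0.4, mode="mortality_only") \
            == pytest.approx(6.0 * 0.6)
        # updating cost is retained in every variant
        assert clutch_size(6.0, 0.0, 1, kappa=0.4, mode="none") \
            == pytest.approx(3.6)

    def test_variants_agree_at_zero_mismatch(self):
        for mode in ("mortality_only", "fecundity_only", "none"):
            assert clutch_size(5.0, 0.0, 1, mode=mode) == \
                pytest.approx(clutch_size(5.0, 0.0, 1, mode="both"))

    @given(r=st.floats(0.01, 20), m=st.floats(0, 5), kappa=st.floats(0, 1),
           dm=st.floats(0, 2))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_decreasing_in_mismatch_and_updating(self, r, m, kappa, dm):
        base = clutch_size(r, m, 0, kappa=kappa)
        assert clutch_size(r, m + dm, 0, kappa=kappa) <= base
        assert clutch_size(r, m, 1, kappa=kappa) <= base
        assert base >= 0.0


class TestMortalityProb:
    @pytest.mark.parametrize(
        "m, r, rho, expected",
        [
            (0.0, 0.0, 0.01, 0.05),        # baseline only
            (0.2, 3.0, 0.01, 0.34),        # 0.05 + 0.2 + 0.09
            (2.0, 10.0, 0.05, 1.0),        # clamped
        ],
    )
    def test_formula(self, m, r, rho, expected):
        assert mortality_prob(m, r, rho=rho) == pytest.approx(expected)

    def test_fecundity_only_variant_drops_mismatch_term(self):
        assert mortality_prob(5.0, 2.0, rho=0.01, mode="fecundity_only") \
            == pytest.approx(0.05 + 0.04)
        assert mortality_prob(5.0, 2.0, rho=0.01, mode="none") \
            == pytest.approx(0.09)

    def test_variants_agree_at_zero_mismatch(self):
        for mode in ("mortality_only", "fecundity_only"):
            assert mortality_prob(0.0, 3.0, mode=mode) == \
                pytest.approx(mortality_prob(0.0, 3.0, mode="both"))

    @given(m=st.floats(0, 5), r=st.floats(0, 15), dm=st.floats(0, 2),
           dr=st.floats(0, 5))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_nondecreasing_and_bounded(self, m, r, dm, dr):
        p = mortality_prob(m, r)
        assert 0.0 <= p <= 1.0
        assert mortality_prob(m + dm, r) >= p
        assert mortality_prob(m, r + dr) >= p

    def test_empirical_death_fraction_matches_probability(self, rng):
        n = 100_000
        p = mortality_prob(0.2, 3.0)  # 0.34
        deaths = (rng.random(n) < p).mean()
        assert abs(deaths - p) < 2.576 * np.sqrt(p * (1 - p) / n)


class TestRecruit:
    def _pop(self, n=2, u=1.0, r=4.0):
        return Population.founders(n, u, r)

    def test_no_vacancies_yields_no_recruits(self, rng):
        u, r, x, idx = recruit(0, self._pop(), np.array([3.0, 1.0]),
                               MutationParams(), rng)
        assert len(u) == len(idx) == 0

    def test_negative_vacancies_is_an_error(self, rng):
        with pytest.raises(ValueError):
            recruit(-1, self._pop(), np.array([1.0, 1.0]), MutationParams(), rng)

    def test_selection_weighted_by_clutch_size(self, rng):
        n = 100_000
        _, _, _, idx = recruit(n, self._pop(), np.array([3.0, 1.0]),
                               MutationParams(sd=0.0), rng)
        freq = (idx == 0).mean()
        assert abs(freq - 0.75) < 2.576 * np.sqrt(0.75 * 0.25 / n)

    def test_zero_weights_leave_vacancies_unfilled(self, rng):
        u, _, _, _ = recruit(5, self._pop(), np.array([0.0, 0.0]),
                             MutationParams(), rng)
        assert len(u) == 0

    def test_eligibility_mask_restricts_parents(self, rng):
        eligible = np.array([False, True])
        _, _, _, idx = recruit(1000, self._pop(), np.array([3.0, 1.0]),
                               MutationParams(sd=0.0), rng, eligible=eligible)
        assert np.all(idx == 1)

    def test_recruits_inherit_mutated_genotypes(self, rng):
        pop = self._pop(n=1, u=2.0, r=3.0)
        u, r, x, idx = recruit(500, pop, np.array([1.0]),
                               MutationParams(sd=0.05), rng)
        assert np.all(u > 0) and np.all(r > 0)
        assert np.log(u / 2.0).std() == pytest.approx(0.05, rel=0.2)


class TestStepPopulation:
    def test_perfect_updaters_have_zero_mismatch(self, rng):
        # huge u: everyone updates every step; epsilon 0: exact phenotype
        pop = Population.founders(200, u_init=50.0, r_init=4.0)
        for E_t in (0.3, -1.2, 2.0):
            pop, out = step_population(pop, E_t, LifeHistoryParams(), 0.0,
                                       MutationParams(), rng)
            assert out.updated_flags.mean() == 1.0
            assert out.mismatch.max() == 0.0

    def test_capacity_is_conserved_under_positive_weights(self, rng):
        pop = Population.founders(150, u_init=1.0, r_init=4.0)
        for _ in range(20):
            pop, out = step_population(pop, rng.normal(), LifeHistoryParams(),
                                       0.2, MutationParams(), rng)
            assert pop.size == pop.capacity == 150
            assert np.all(out.clutch_sizes >= 0)
            assert out.n_recruits == out.death_flags.sum()

    def test_total_dieoff_extinguishes_population(self, rng):
        # rho so high that every adult dies; survivors-pool recruitment
        # leaves nobody to draw from
        life = LifeHistoryParams(rho=0.05)
        pop = Population.founders(100, u_init=1.0, r_init=7.0)
        pop, out = step_population(pop, 0.0, life, 0.0, MutationParams(), rng)
        assert out.death_flags.all()
        assert out.extinct and pop.size == 0

    def test_all_parents_pool_replaces_population_in_one_step(self, rng):
        # under the all-parents option, dead adults reproduced first, so a
        # positive clutch weight refills the population in the same step
        life = LifeHistoryParams(rho=0.05, recruit_pool="all_parents")
        pop = Population.founders(100, u_init=1.0, r_init=7.0)
        new_pop, out = step_population(pop, 0.0, life, 0.0, MutationParams(),
                                       rng)
        assert out.death_flags.all()
        assert np.all(out.clutch_sizes > 0)
        assert new_pop.size == 100
        assert np.all(new_pop.age == 0) and np.all(new_pop.T_u == NEWBORN)

    def test_ageing_and_clock_increment_before_update_decision(self, rng):
        # one adult that certainly does not update (tiny u, short T_u)
        pop = Population.founders(1, u_init=1e-9, r_init=1.0)
        life = LifeHistoryParams(alpha0=0.0, rho=0.0, mismatch_mode="none")
        pop, out = step_population(pop, 0.0, life, 0.0, MutationParams(), rng)
        assert out.updated_flags[0] == 1 and pop.T_u[0] == 0  # forced newborn
        pop, out = step_population(pop, 0.0, life, 0.0, MutationParams(), rng)
        assert out.updated_flags[0] == 0
        assert pop.T_u[0] == 1 and pop.age[0] == 2

    def test_empty_population_cannot_be_stepped(self, rng):
        pop = Population.founders(1, 1.0, 1.0)
        with pytest.raises(ValueError):
            empty = Population(u=np.empty(0), r=np.empty(0), x=np.empty(0),
                               T_u=np.empty(0, dtype=int),
                               age=np.empty(0, dtype=int),
                               ids=np.empty(0, dtype=int), capacity=1)
            step_population(empty, 0.0, LifeHistoryParams(), 0.0,
                            MutationParams(), rng)

    def test_homogeneous_death_fraction_matches_analytic(self, rng):
        # u huge + epsilon 0 pins m = 0, so p_death = alpha0 + rho r^2
        pop = Population.founders(100_000, u_init=50.0, r_init=3.0)
        life = LifeHistoryParams()
        p = mortality_prob(0.0, 3.0, rho=life.rho, alpha0=life.alpha0)
        _, out = step_population(pop, 0.0, life, 0.0, MutationParams(), rng)
        frac = out.death_flags.mean()
        assert abs(frac - p) < 2.576 * np.sqrt(p * (1 - p) / pop.capacity)


class TestLifeHistoryParams:
    @pytest.mark.parametrize("kwargs", [
        {"kappa": 1.5}, {"rho": -0.1}, {"alpha0": 2.0},
        {"mismatch_mode": "bogus"}, {"recruit_pool": "bogus"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LifeHistoryParams(**kwargs)
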