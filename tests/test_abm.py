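"""Mechanics of the individual-based simulator: per-attempt fitness, flood
schedules, mutation, recruitment, generation stepping and whole-replicate
runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from floodnest import (
    EnvironmentRegime,
    FloodSchedule,
    LifeHistory,
    PopulationState,
    SimulationConfig,
    draw_flood_schedule,
    initialize_population,
    lifetime_reproductive_success,
    mutate_offspring,
    nest_fitness,
    recruit,
    run_replicate,
    step_generation,
)
from floodnest.abm import _reproduce


def make_schedule(flags, height=0.4):
    flooded = np.asarray(flags, dtype=bool)
    heights = np.where(flooded, height, 0.0)
    return FloodSchedule(flooded=flooded, heights=heights)


class TestNestFitness:
    @pytest.mark.parametrize(
        "z, level, expected",
        [
            (0.5, 0.4, 0.5),   # above water: predation cost only
            (0.3, 0.4, 0.0),   # below water: nest destroyed
            (0.3, 0.0, 0.7),   # no flood
            (0.4, 0.4, 0.6),   # at the water line the nest survives
            (0.0, 0.0, 1.0),
            (1.0, 0.0, 0.0),
        ],
    )
    def test_values(self, z, level, expected):
        assert nest_fitness(z, level) == pytest.approx(expected)

    def test_out_of_range_phenotype_rejected(self):
        with pytest.raises(ValueError, match="phenotype"):
            nest_fitness(1.2, 0.0)
        with pytest.raises(ValueError, match="phenotype"):
            nest_fitness(np.array([0.5, -0.1]), 0.0)


class TestFloodSchedule:
    def test_no_floods_at_p_zero(self, rng):
        sched = draw_flood_schedule(EnvironmentRegime(p=0.0), 5, rng)
        assert not sched.flooded.any()
        assert np.all(sched.heights == 0.0)

    def test_all_floods_at_p_one(self, rng):
        sched = draw_flood_schedule(EnvironmentRegime(p=1.0, h=0.4), 3, rng)
        assert sched.flooded.all()
        assert np.all(sched.heights == 0.4)

    def test_flood_frequency_follows_binomial_law(self, rng):
        n_draws = 10_000
        hits = sum(
            draw_flood_schedule(EnvironmentRegime(p=0.15), 1, rng).flooded[0]
            for _ in range(n_draws)
        )
        assert stats.binomtest(int(hits), n_draws, 0.15).pvalue > 1e-3

    def test_variable_heights_truncated_and_centred(self, rng):
        regime = EnvironmentRegime(p=1.0, h=0.4, flood_height_sd=0.1)
        heights = np.concatenate(
            [draw_flood_schedule(regime, 10, rng).heights for _ in range(200)]
        )
        assert np.all((heights >= 0.0) & (heights <= 1.0))
        assert heights.std() > 0.05  # actually varying
        assert abs(heights.mean() - 0.4) < 0.01

    def test_invalid_attempts(self, rng):
        with pytest.raises(ValueError):
            draw_flood_schedule(EnvironmentRegime(), 0, rng)


class TestLifetimeReproductiveSuccess:
    def test_no_floods_hand_value(self, rng):
        # two attempts, z = 0.2: round(5*0.8 + 5*0.8) = 8
        sched = make_schedule([False, False])
        assert lifetime_reproductive_success(0.2, sched, s=1.0, c=5.0, rng=rng) == 8

    def test_affected_below_water_gets_zero(self, rng):
        sched = make_schedule([True])
        assert lifetime_reproductive_success(0.2, sched, s=1.0, c=5.0, rng=rng) == 0

    def test_half_rounds_up(self, rng):
        # z = 0.5 survives the flood: round(5*0.5) = round(2.5) -> 3
        sched = make_schedule([True])
        assert lifetime_reproductive_success(0.5, sched, s=1.0, c=5.0, rng=rng) == 3

    def test_scope_zero_ignores_floods(self, rng):
        sched = make_schedule([True, True, True])
        assert lifetime_reproductive_success(0.2, sched, s=0.0, c=5.0, rng=rng) == 12

    def test_vectorized_matches_scalar_without_scope_randomness(self, rng):
        # s = 1 removes the only per-individual random draw, so the scalar
        # and vectorized paths must agree exactly, floods included
        z = rng.random(100)
        sched = make_schedule([True, False, True])
        counts, destroyed = _reproduce(z, sched, s=1.0, c=5.0, rng=rng)
        expected = [
            lifetime_reproductive_success(zi, sched, s=1.0, c=5.0, rng=rng)
            for zi in z
        ]
        assert counts.tolist() == expected
        assert np.array_equal(destroyed, z < 0.4)


class TestDeterministicFitnessOracle:
    """With no floods, every fitness is the closed form round(n*c*(1-z))."""

    @pytest.mark.parametrize("n, c", [(1, 5.0), (2, 5.0), (5, 5.0), (3, 2.0)])
    def test_matches_scalar_brute_force(self, n, c, rng):
        z = rng.random(100)
        sched = make_schedule([False] * n)
        counts, _ = _reproduce(z, sched, s=1.0, c=c, rng=rng)
        brute = [int(np.floor(n * c * (1.0 - zi) + 0.5)) for zi in z]
        assert counts.tolist() == brute


class TestMutation:
    def test_no_mutation_is_identity(self, rng):
        for z in (0.0, 0.33, 1.0):
            assert mutate_offspring(z, m=0.0, m_size=0.05, rng=rng) == z

    def test_clamped_to_unit_interval(self, rng):
        for parent in (0.0, 1.0):
            vals = [
                mutate_offspring(parent, m=1.0, m_size=0.5, rng=rng)
                for _ in range(200)
            ]
            assert all(0.0 <= v <= 1.0 for v in vals)

    def test_deviate_spread_matches_configured_sd(self, rng):
        parent = 0.5
        draws = np.array(
            [mutate_offspring(parent, 1.0, 0.05, rng) for _ in range(100_000)]
        )
        assert np.abs((draws - parent).std() - 0.05) < 0.001


class TestRecruitment:
    def test_under_capacity_keeps_everyone(self, rng):
        pool = rng.random(4000)
        assert recruit(pool, 5000, rng) is pool

    def test_over_capacity_caps_exactly(self, rng):
        pool = np.arange(6000, dtype=float)
        kept = recruit(pool, 5000, rng)
        assert kept.size == 5000
        assert np.unique(kept).size == 5000  # without replacement

    def test_inclusion_is_uniform(self, rng):
        # mark half the pool; retained count is hypergeometric with
        # mean 2500 and sd ~20.4 — allow 5 sigma
        pool = np.concatenate([np.zeros(3000), np.ones(3000)])
        kept = recruit(pool, 5000, rng)
        assert abs(kept.sum() - 2500) < 5 * 20.5

    def test_empty_pool_means_extinction(self, rng):
        assert recruit(np.array([]), 5000, rng).size == 0


@settings(derandomize=True, max_examples=50)
@given(size=st.integers(0, 200), k=st.integers(0, 200), seed=st.integers(0, 10_000))
def test_recruitment_size_and_membership(size, k, seed):
    rng = np.random.default_rng(seed)
    pool = rng.random(size)
    kept = recruit(pool, k, rng)
    assert kept.size == min(size, k)
    assert np.all(np.isin(kept, pool))


class TestStepGeneration:
    def test_same_seed_same_successor(self, small_config):
        states = []
        for _ in range(2):
            rng = np.random.default_rng(4321)
            state = initialize_population(small_config, rng)
            for _ in range(5):
                state = step_generation(state, small_config, rng)
            states.append(state)
        assert np.array_equal(states[0].phenotypes, states[1].phenotypes)
        assert states[0].generation == states[1].generation == 5

    def test_selection_weights_without_floods_or_mutation(self):
        # with p=0, m=0 and no cap, offspring counts are exactly the
        # deterministic weights round(n*c*(1-z)) for each parent
        z = np.linspace(0.05, 0.95, 10)
        config = SimulationConfig(
            regime=EnvironmentRegime(p=0.0),
            life_history=LifeHistory(n=2, c=5.0),
            n0=10,
            k=10_000,
            m=0.0,
        )
        state = PopulationState(phenotypes=z)
        nxt = step_generation(state, config, np.random.default_rng(0))
        expected_counts = np.floor(2 * 5.0 * (1.0 - z) + 0.5).astype(int)
        got = {v: int((nxt.phenotypes == v).sum()) for v in z}
        assert got == dict(zip(z.tolist(), expected_counts.tolist()))

    def test_universal_flood_kills_low_nesters(self):
        config = SimulationConfig(
            regime=EnvironmentRegime(p=1.0, s=1.0, h=0.4),
            life_history=LifeHistory(n=1),
            n0=20,
            k=100,
        )
        state = PopulationState(phenotypes=np.full(20, 0.2))
        nxt = step_generation(state, config, np.random.default_rng(0))
        assert nxt.extinct

    def test_extinction_is_absorbing(self, small_config):
        rng = np.random.default_rng(0)
        state = PopulationState(phenotypes=np.array([]))
        for expected_gen in (1, 2, 3):
            state = step_generation(state, small_config, rng)
            assert state.extinct and state.generation == expected_gen

    def test_heredity_without_mutation_adds_no_phenotypes(self, small_config):
        config = small_config.replace(m=0.0)
        rng = np.random.default_rng(11)
        state = initialize_population(config, rng)
        founders = set(state.phenotypes.tolist())
        for _ in range(20):
            state = step_generation(state, config, rng)
            assert set(state.phenotypes.tolist()) <= founders


class TestCapacityAndBounds:
    def test_capacity_and_phenotype_bounds_hold_every_generation(self):
        config = SimulationConfig(
            regime=EnvironmentRegime(p=0.2, s=0.9),
            life_history=LifeHistory(n=3),
            n0=500,
            k=500,
            m=0.02,  # frequent mutation to exercise clamping
            generations=200,
            seed=3,
        )
        rng = np.random.default_rng(3)
        state = initialize_population(config, rng)
        for _ in range(200):
            state = step_generation(state, config, rng)
            assert state.size <= config.k
            if state.size:
                assert state.phenotypes.min() >= 0.0
                assert state.phenotypes.max() <= 1.0


class TestScopeLaw:
    def test_affected_fraction_is_binomial(self, rng):
        # one flooded attempt over 10,000 low nests: the number destroyed
        # (fitness 0) must be consistent with Binomial(N, s)
        z = np.full(10_000, 0.2)
        sched = make_schedule([True])
        counts, destroyed = _reproduce(z, sched, s=0.7, c=5.0, rng=rng)
        assert np.array_equal(destroyed, counts == 0)
        assert stats.binomtest(int(destroyed.sum()), 10_000, 0.7).pvalue > 1e-3


class TestRunReplicate:
    def test_zero_generations_records_initial_state_only(self):
        config = SimulationConfig(n0=5000, generations=0, seed=8)
        res = run_replicate(config)
        assert len(res.mean_z) == 1
        assert res.pop_size[0] == 5000
        assert abs(res.mean_z[0] - 0.5) < 0.02  # uniform founding

    def test_reproducible_with_same_seed(self, small_config):
        a = run_replicate(small_config)
        b = run_replicate(small_config)
        assert np.array_equal(a.mean_z, b.mean_z, equal_nan=True)
        assert np.array_equal(a.pop_size, b.pop_size)
        assert np.array_equal(a.flood_events, b.flood_events)
        assert a.extinct == b.extinct

    def test_trajectory_truncated_at_extinction(self):
        config = SimulationConfig(
            regime=EnvironmentRegime(p=1.0, s=1.0, h=0.95),
            life_history=LifeHistory(n=1),
            n0=50,
            k=50,
            generations=100,
            seed=2,
        )
        res = run_replicate(config)
        # nearly all founders sit below 0.95, and survivors' clutches round
        # to zero (c*(1-z) < 0.5 for z > 0.9), so extinction is immediate
        assert res.extinct
        assert res.extinction_generation == len(res.mean_z) - 1
        assert res.pop_size[-1] == 0
        assert np.isnan(res.mean_z[-1])

    def test_flood_log_heights_constant_by_default(self, small_config):
        res = run_replicate(small_config)
        assert res.flood_events.shape[1] == 3
        if len(res.flood_events):
            assert np.all(res.flood_events[:, 2] == small_config.regime.h)

    def test_selection_drives_ground_nesting_without_floods(self):
        # without floods the predation gradient pushes nest height to the
        # lowest fitness-equivalent band; with 3 attempts that band is
        # [0, 1/30], well under the low-nesting threshold
        config = SimulationConfig(
            regime=EnvironmentRegime(p=0.0),
            life_history=LifeHistory(n=3),
            n0=1000,
            k=1000,
            generations=400,
            seed=5,
        )
        res = run_replicate(config)
        assert not res.extinct
        assert res.final_mean_z < 0.05


class TestOverlapVariant:
    def test_adults_persist_and_capacity_still_binds(self):
        config = SimulationConfig(
            regime=EnvironmentRegime(p=0.2, s=1.0),
            life_history=LifeHistory(n=1, overlap=True, adult_survival=0.8),
            n0=200,
            k=200,
            generations=50,
            seed=6,
        )
        rng = np.random.default_rng(6)
        state = initialize_population(config, rng)
        assert state.ages is not None
        for _ in range(50):
            state = step_generation(state, config, rng)
            assert state.size <= config.k
        assert state.ages.max() >= 1  # some adults survived at least a year

    def test_adult_mortality_kills_flooded_low_nesters(self):
        # all-low population, universal flood, guaranteed adult survival:
        # with adult_mortality the adults die with their nests
        config = SimulationConfig(
            regime=EnvironmentRegime(p=1.0, s=1.0, h=0.4),
            life_history=LifeHistory(
                n=1, overlap=True, adult_survival=1.0, adult_mortality=True
            ),
            n0=30,
            k=100,
        )
        state = PopulationState(
            phenotypes=np.full(30, 0.2), ages=np.zeros(30, dtype=np.int64)
        )
        nxt = step_generation(state, config, np.random.default_rng(0))
        assert nxt.extinct
        # without adult_mortality the adults ride out the flood
        config2 = SimulationConfig(
            regime=config.regime,
            life_history=LifeHistory(n=1, overlap=True, adult_survival=1.0),
            n0=30,
            k=100,
        )
        nxt2 = step_generation(state, config2, np.random.default_rng(0))
        assert nxt2.size == 30
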