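import numpy as np
import pytest

from tagforge.constraints import INFINITY, ConstraintProfile
from tagforge.ga import (
    GAConfig,
    GAState,
    dynamic_mutation_rate,
    evolve,
    fitness,
    init_population_even,
    log_to_tsv,
    maybe_reinitialize,
    run_experiments,
    three_point_crossover,
    tournament_select,
)

FAST = GAConfig(population_size=80, generations=40, seed=0)


class TestInitPopulationEven:
    def test_known_spacings(self):
        assert init_population_even(4, 2) == ["AA", "CA", "GA", "TA"]
        assert init_population_even(2, 1) == ["A", "G"]

    def test_spacing_differs_by_at_most_one(self):
        from tagforge.sequences import sequence_to_index

        for k, n in [(7, 3), (500, 5), (13, 4)]:
            idx = [sequence_to_index(s) for s in init_population_even(k, n)]
            gaps = np.diff(idx)
            assert gaps.max() - gaps.min() <= 1

    def test_infeasible_population(self):
        with pytest.raises(ValueError):
            init_population_even(17, 2)


class TestFitness:
    def test_lethal_on_single_tag_violation(self):
        profile = ConstraintProfile(d=1, gc_mode="off", continuity_max=2)
        assert fitness("AAATTG", [], profile) == 0.0

    def test_tte_when_rules_pass(self):
        profile = ConstraintProfile(d=1, gc_mode="off", continuity_max=10)
        assert fitness("ACTG", ["CAGT", "GAGT"], profile) == 3

    def test_sentinel_on_empty_set(self):
        profile = ConstraintProfile(d=3, gc_mode="off", continuity_max=10)
        assert fitness("ACTG", [], profile) == INFINITY

    def test_banked_duplicate_is_lethal(self):
        profile = ConstraintProfile(d=1, gc_mode="off", continuity_max=10)
        assert fitness("ACTG", ["ACTG", "CAGT"], profile) == 0.0


class TestDynamicMutationRate:
    @pytest.mark.parametrize(
        "fit, mean, rate", [(5, 3.2, 0.01), (3.2, 3.2, 0.03), (1, 3.2, 0.3)]
    )
    def test_bands(self, fit, mean, rate):
        assert dynamic_mutation_rate(fit, mean) == rate

    def test_sentinel_gets_low_rate(self):
        assert dynamic_mutation_rate(INFINITY, 3.2) == 0.01


class TestTournament:
    def test_higher_fitness_wins(self):
        rng = np.random.default_rng(0)
        fits = np.array([3.0, 1.0])
        winners = tournament_select(fits, GAConfig(population_size=2), rng)
        # whenever both contestants differ, index 0 must win
        assert set(winners.tolist()) <= {0, 1}
        draws_differ = [w for w in winners]
        assert all(fits[w] >= 1.0 for w in draws_differ)

    def test_identical_population_returns_that_individual(self):
        rng = np.random.default_rng(1)
        fits = np.full(10, 2.0)
        winners = tournament_select(fits, GAConfig(population_size=10), rng)
        assert all(0 <= w < 10 for w in winners)

    def test_tie_break_is_empirically_fair(self):
        """Over 10,000 two-way ties the winner frequencies are 50/50 +/- 2%."""
        rng = np.random.default_rng(123)
        fits = np.array([2.0, 2.0])
        config = GAConfig(population_size=2, tournament_fraction=1.0)
        wins0 = 0
        trials = 0
        for _ in range(5000):
            draws = tournament_select(fits, config, rng)
            wins0 += int((draws == 0).sum())
            trials += len(draws)
        assert trials >= 10_000
        assert abs(wins0 / trials - 0.5) < 0.02


class TestCrossover:
    def test_forced_alternating_segments(self):
        config = GAConfig(crossover_rate=1.0)

        class CutRng:
            def random(self):
                return 0.0

            def choice(self, arr, size=None, replace=True):
                return np.array([1, 2, 3])

        c1, c2 = three_point_crossover("AAAA", "TTTT", config, CutRng())
        assert (c1, c2) == ("ATAT", "TATA")

    def test_zero_rate_copies_parents(self):
        rng = np.random.default_rng(0)
        config = GAConfig(crossover_rate=0.0)
        assert three_point_crossover("ACGT", "TGCA", config, rng) == ("ACGT", "TGCA")

    def test_columns_conserved(self):
        rng = np.random.default_rng(5)
        config = GAConfig(crossover_rate=1.0)
        p1, p2 = "ACGTACG", "TTGACCA"
        for _ in range(50):
            c1, c2 = three_point_crossover(p1, p2, config, rng)
            for pos in range(len(p1)):
                assert sorted([c1[pos], c2[pos]]) == sorted([p1[pos], p2[pos]])

    def test_short_parents_fall_back_to_single_point(self):
        rng = np.random.default_rng(2)
        config = GAConfig(crossover_rate=1.0)
        c1, c2 = three_point_crossover("ACG", "TGA", config, rng)
        assert len(c1) == len(c2) == 3 and set(c1 + c2) <= set("ACGT")


class TestReinitialization:
    def test_below_threshold_keeps_population(self):
        rng = np.random.default_rng(0)
        pop = np.zeros((10, 4), dtype=np.uint8)
        state = GAState(stall_counter=5)
        out = maybe_reinitialize(pop, state, GAConfig(), rng)
        assert out is pop and not state.reinit_used

    def test_fires_once_then_never_again(self):
        rng = np.random.default_rng(0)
        pop = np.zeros((30, 6), dtype=np.uint8)
        state = GAState(stall_counter=20)
        out = maybe_reinitialize(pop, state, GAConfig(), rng)
        assert state.reinit_used and not np.array_equal(out, pop)
        assert out.shape == pop.shape and out.dtype == np.uint8 and out.max() <= 3
        state.stall_counter = 99
        again = maybe_reinitialize(out, state, GAConfig(), rng)
        assert again is out  # "only once"

    def test_off_policy_never_fires(self):
        rng = np.random.default_rng(0)
        pop = np.zeros((10, 4), dtype=np.uint8)
        state = GAState(stall_counter=1000)
        assert maybe_reinitialize(pop, state, GAConfig(reinit_policy="off"), rng) is pop


class TestEvolve:
    def test_seeded_determinism(self):
        profile = ConstraintProfile(d=3, gc_mode="range", complementarity="self")
        s1, log1 = evolve(6, profile, FAST)
        s2, log2 = evolve(6, profile, FAST)
        assert s1.tags == s2.tags
        assert log_to_tsv(log1) == log_to_tsv(log2)

    def test_distance_one_collects_distinct_words(self):
        profile = ConstraintProfile(d=1, gc_mode="off", continuity_max=10)
        tag_set, _ = evolve(4, profile, GAConfig(population_size=60, generations=15, seed=3))
        assert len(tag_set.tags) == len(set(tag_set.tags))
        assert len(tag_set) > 30
        assert tag_set.validate().passed

    def test_infeasible_profile_raises_before_evolution(self):
        with pytest.raises(ValueError):
            evolve(4, ConstraintProfile(d=6), FAST)

    @pytest.mark.parametrize("template_kwargs", [
        dict(gc_mode="range", complementarity="self"),
        dict(gc_mode="fixed", complementarity="self"),
        dict(gc_mode="fixed", complementarity="cross"),
        dict(gc_mode="off", complementarity="none", continuity_max=10),
    ])
    @pytest.mark.parametrize("n,d", [(4, 3), (5, 4), (6, 5), (7, 6), (8, 6), (8, 3)])
    def test_closure_every_emitted_set_validates(self, n, d, template_kwargs):
        """Whatever the profile, the designer's output passes the
        independent validator under that same profile."""
        profile = ConstraintProfile(d=d, **template_kwargs)
        tag_set, log = evolve(n, profile, FAST)
        report = tag_set.validate()
        assert report.passed, report.as_dict()
        assert log[-1].set_size == len(tag_set)

    def test_log_shape_and_monotone_set_size(self):
        profile = ConstraintProfile(d=3, gc_mode="range", complementarity="self")
        _, log = evolve(5, profile, FAST)
        assert len(log) == FAST.generations
        sizes = [rec.set_size for rec in log]
        assert sizes == sorted(sizes)
        tsv = log_to_tsv(log)
        assert tsv.splitlines()[0] == "generation\tset_size\tmean_fitness\tmax_fitness"
        assert len(tsv.splitlines()) == FAST.generations + 1


class TestRunExperiments:
    def test_single_run_identical_to_evolve(self):
        profile = ConstraintProfile(d=3, gc_mode="range", complementarity="self")
        res = run_experiments(5, profile, FAST, runs=1)
        direct, _ = evolve(5, profile, FAST)
        assert res.best.tags == direct.tags
        assert res.sizes == [len(direct)]

    def test_max_dominates_every_run_and_is_monotone_in_runs(self):
        profile = ConstraintProfile(d=4, gc_mode="range", complementarity="self")
        res3 = run_experiments(6, profile, FAST, runs=3)
        res5 = run_experiments(6, profile, FAST, runs=5)
        assert res3.max_size == max(res3.sizes)
        assert res5.max_size >= res3.max_size
        assert res5.sizes[:3] == res3.sizes  # same seeds, same outcomes

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5)
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            run_experiments(4, ConstraintProfile(d=3), FAST, runs=0)
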