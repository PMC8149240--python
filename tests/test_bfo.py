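import numpy as np
import pytest

from swarmstack.bfo import (Bacterium, BFOConfig, chemotaxis_step,
                            elimination_dispersal, reproduction,
                            select_features_bfo, swarming_term,
                            tumble_direction)
from swarmstack.fitness import FitnessValue


class TestTumble:
    def test_unit_norm(self):
        rng = np.random.default_rng(0)
        for p in (1, 2, 7, 30):
            d = tumble_direction(p, rng)
            assert abs(np.linalg.norm(d) - 1.0) < 1e-12

    def test_scalar_case_is_plus_or_minus_one(self):
        rng = np.random.default_rng(1)
        vals = {float(tumble_direction(1, rng)[0]) for _ in range(50)}
        assert vals <= {-1.0, 1.0} and len(vals) == 2

    def test_isotropy(self):
        rng = np.random.default_rng(2)
        draws = np.stack([tumble_direction(3, rng) for _ in range(10_000)])
        se = draws.std(0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(0)) < 3 * se)


class TestSwarming:
    def test_attract_and_repel_cancel_at_zero_distance(self):
        cfg = BFOConfig(d_attract=0.1, h_repel=0.1)
        b = Bacterium(position=np.array([0.5, 0.5]))
        assert swarming_term(b.position, [b], cfg) == pytest.approx(0.0)

    def test_vanishes_far_from_the_herd(self):
        cfg = BFOConfig()
        herd = [Bacterium(position=np.zeros(2))]
        far = np.full(2, 1e6)
        assert swarming_term(far, herd, cfg) == pytest.approx(0.0, abs=1e-30)

    def test_matches_two_loop_recomputation(self):
        rng = np.random.default_rng(3)
        cfg = BFOConfig(d_attract=0.13, w_attract=0.4, h_repel=0.07, w_repel=8.0)
        herd = [Bacterium(position=rng.uniform(size=4)) for _ in range(5)]
        theta = rng.uniform(size=4)
        expected = 0.0
        for b in herd:
            sq = sum((theta[k] - b.position[k]) ** 2 for k in range(4))
            expected += -cfg.d_attract * np.exp(-cfg.w_attract * sq)
            expected += cfg.h_repel * np.exp(-cfg.w_repel * sq)
        assert swarming_term(theta, herd, cfg) == pytest.approx(expected, rel=1e-12)


class TestChemotaxis:
    def test_zero_step_length_is_a_single_evaluation(self):
        cfg = BFOConfig(L=0.0, swarming=False, seed=0)
        calls = []

        def fitness(mask):
            calls.append(mask.bits)
            return FitnessValue(0.5, mask.cardinality)

        b = Bacterium(position=np.array([0.3, 0.8]), J_last=0.5)
        out = chemotaxis_step(b, [b], cfg, fitness, np.random.default_rng(0))
        np.testing.assert_array_equal(out.position, b.position)
        assert len(calls) == 1

    def test_worsening_tumble_takes_no_swim(self):
        cfg = BFOConfig(L=0.1, N_s=4, swarming=False)
        calls = []

        def fitness(mask):
            calls.append(1)
            return FitnessValue(0.1, mask.cardinality)   # objective 0.9

        b = Bacterium(position=np.array([0.3, 0.8]), J_last=0.2)
        chemotaxis_step(b, [b], cfg, fitness, np.random.default_rng(1))
        assert len(calls) == 1                            # tumble only

    def test_monotone_objective_hits_the_swim_cap(self):
        # every evaluation scores strictly better than the last, so the swim
        # loop must run to its cap
        cfg = BFOConfig(L=0.05, N_s=4, swarming=False)
        b = Bacterium(position=np.array([0.5]), J_last=1.0)
        seen = []

        def fitness(mask):
            seen.append(1)
            return FitnessValue(min(cfg.L * len(seen), 1.0), 1)

        out = chemotaxis_step(b, [b], cfg, fitness, np.random.default_rng(0))
        assert len(seen) == 1 + cfg.N_s                   # tumble + N_s swims
        assert abs(out.position[0] - 0.5) == pytest.approx(cfg.L * (1 + cfg.N_s))


class TestReproduction:
    def test_minimal_case_duplicates_the_healthier(self):
        cfg = BFOConfig(S=2, S_r=1)
        good = Bacterium(position=np.array([0.1]), health=1.0)
        bad = Bacterium(position=np.array([0.9]), health=5.0)
        out = reproduction([bad, good], cfg)
        assert len(out) == 2
        assert all(b.position[0] == 0.1 for b in out)
        assert all(b.health == 0.0 for b in out)

    @pytest.mark.parametrize("S", [4, 8, 20])
    def test_population_size_conserved(self, S):
        rng = np.random.default_rng(4)
        cfg = BFOConfig(S=S)
        herd = [Bacterium(position=rng.uniform(size=3), health=rng.uniform())
                for _ in range(S)]
        assert len(reproduction(herd, cfg)) == S

    def test_no_new_positions_invented(self):
        rng = np.random.default_rng(5)
        cfg = BFOConfig(S=6)
        herd = [Bacterium(position=rng.uniform(size=2), health=rng.uniform())
                for _ in range(6)]
        inputs = {tuple(b.position) for b in herd}
        out = reproduction(herd, cfg)
        assert {tuple(b.position) for b in out} <= inputs


class TestEliminationDispersal:
    def test_probability_zero_keeps_the_herd(self):
        rng = np.random.default_rng(6)
        herd = [Bacterium(position=rng.uniform(size=2)) for _ in range(5)]
        cfg = BFOConfig(P_ed=0.0)
        out = elimination_dispersal(herd, cfg, np.random.default_rng(0))
        assert all(a is b for a, b in zip(out, herd))

    def test_probability_one_redraws_everything(self):
        rng = np.random.default_rng(7)
        herd = [Bacterium(position=rng.uniform(size=3)) for _ in range(5)]
        cfg = BFOConfig(P_ed=1.0)
        out = elimination_dispersal(herd, cfg, np.random.default_rng(1))
        assert all(b.position.min() >= 0 and b.position.max() <= 1 for b in out)
        assert all(not np.array_equal(a.position, b.position)
                   for a, b in zip(herd, out))

    def test_empirical_dispersal_fraction(self):
        cfg = BFOConfig(P_ed=0.25)
        rng = np.random.default_rng(8)
        herd = [Bacterium(position=np.full(2, 0.5)) for _ in range(40)]
        dispersed = 0
        trials = 1000
        for _ in range(trials):
            out = elimination_dispersal(herd, cfg, rng)
            dispersed += sum(o is not b for o, b in zip(out, herd))
        n = trials * len(herd)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(dispersed / n - 0.25) < 3 * se


class TestSelect:
    def test_trace_is_non_decreasing(self, small_train, small_evaluator):
        cfg = BFOConfig(S=6, N_c=3, N_re=2, N_ed=1, seed=0)
        _, _, trace = select_features_bfo(small_train, cfg, small_evaluator)
        assert trace and all(a <= b for a, b in zip(trace, trace[1:]))

    def test_evaluation_budget_via_cache(self, small_train):
        from swarmstack.fitness import FitnessEvaluator
        ev = FitnessEvaluator(small_train, folds=3, seed=5)
        cfg = BFOConfig(S=6, N_c=3, N_s=2, N_re=2, N_ed=1, seed=1)
        select_features_bfo(small_train, cfg, ev)
        bound = cfg.S * cfg.N_ed * cfg.N_re * cfg.N_c * (1 + cfg.N_s) + cfg.S
        assert ev.evaluation_count <= bound

    def test_population_size_invariant_and_determinism(self, small_train,
                                                       small_evaluator):
        cfg = BFOConfig(S=4, N_c=2, N_re=2, N_ed=2, seed=3)
        a = select_features_bfo(small_train, cfg, small_evaluator)
        b = select_features_bfo(small_train, cfg, small_evaluator)
        assert a[0].bits == b[0].bits and a[2] == b[2]
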