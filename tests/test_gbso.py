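"""Grasshopper swarm feature selection: force law, schedule, wrapper, recovery."""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from szdetect.gbso import (
    GBSOConfig,
    Grasshopper,
    Swarm,
    binarize_mask,
    coefficient_schedule,
    comfort_zone_boundary,
    gbso_select,
    make_planted_features,
    social_force,
    social_force_peak,
    subset_fitness,
    update_positions,
)
from szdetect.signal_io import LabeledDataset


class TestSocialForce:
    def test_zero_at_comfort_zone_boundary(self):
        assert social_force(2.079) == pytest.approx(0.0, abs=1e-3)

    def test_at_zero_distance_equals_f_minus_one(self):
        assert social_force(0.0) == pytest.approx(-0.5)

    def test_sign_structure(self):
        assert social_force(1.0) < 0      # repulsion inside the comfort zone
        assert social_force(3.0) > 0      # attraction beyond it

    def test_peak_at_three_ln_three(self):
        grid = np.linspace(1e-3, 10, 100001)
        argmax = grid[np.argmax(social_force(grid))]
        assert argmax == pytest.approx(3 * math.log(3), abs=1e-2)
        assert social_force_peak() == pytest.approx(3 * math.log(3), rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            social_force(-0.1)


class TestComfortZone:
    def test_default_parameters_give_printed_boundary(self):
        assert comfort_zone_boundary(0.5, 1.5) == pytest.approx(3 * math.log(2),
                                                                rel=1e-12)
        assert comfort_zone_boundary(0.5, 1.5) == pytest.approx(2.0794, abs=1e-4)

    def test_other_length_scale(self):
        assert comfort_zone_boundary(0.5, 3.0) == pytest.approx(
            3 * math.log(2) / 2, abs=1e-4)

    def test_bisection_agrees_with_closed_form(self):
        root = bisect(lambda r: social_force(r, 0.5, 1.5), 1e-3, 20, xtol=1e-12)
        assert root == pytest.approx(comfort_zone_boundary(0.5, 1.5), abs=1e-8)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            comfort_zone_boundary(1.5, 1.5)
        with pytest.raises(ValueError):
            comfort_zone_boundary(0.5, 0.9)


class TestCoefficientSchedule:
    @pytest.mark.parametrize("fitness,avg", [(1.0, 0.5), (0.1, 0.5)])
    def test_endpoints_coincide(self, fitness, avg):
        assert coefficient_schedule(0, 100, 1.0, 1e-5, fitness, avg) == 1.0
        assert coefficient_schedule(100, 100, 1.0, 1e-5, fitness, avg) == \
            pytest.approx(1e-5, rel=1e-9)

    def test_mid_schedule_hand_values(self):
        linear = coefficient_schedule(50, 100, 1.0, 1e-5, 0.9, 0.5)
        quadratic = coefficient_schedule(50, 100, 1.0, 1e-5, 0.1, 0.5)
        assert linear == pytest.approx(0.500005, abs=1e-9)
        assert quadratic == pytest.approx(0.2500075, abs=1e-9)

    def test_quadratic_branch_dominated_by_linear(self):
        """Better-than-average members always get the smaller coefficient."""
        for it in range(1, 100):
            lin = coefficient_schedule(it, 100, 1.0, 1e-5, 1.0, 0.5)
            quad = coefficient_schedule(it, 100, 1.0, 1e-5, 0.0, 0.5)
            assert quad < lin

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ValueError):
            coefficient_schedule(101, 100, 1.0, 1e-5, 0.5, 0.5)


class TestBinarize:
    def test_threshold_with_tie_selecting(self):
        mask = binarize_mask(np.array([0.7, 0.2, 0.5]), 0.5)
        assert mask.tolist() == [True, False, True]

    def test_all_below_threshold(self):
        assert not binarize_mask(np.full(5, 0.49), 0.5).any()

    def test_zero_threshold_selects_all(self):
        assert binarize_mask(np.zeros(4), 0.0).all()


class TestUpdatePositions:
    def _swarm(self, positions, fitnesses, best):
        members = [Grasshopper(position=np.array(p, dtype=float), fitness=f)
                   for p, f in zip(positions, fitnesses)]
        return Swarm(members=members,
                     global_best_position=np.array(best, dtype=float),
                     global_best_fitness=min(fitnesses), iteration=50)

    def test_single_member_collapses_to_global_best(self):
        swarm = self._swarm([[0.8]], [0.3], [0.2])
        cfg = GBSOConfig(N=1, it_max=100, jump_prob=0.0, seed=0)
        update_positions(swarm, cfg, np.random.default_rng(0))
        assert swarm.members[0].position == pytest.approx([0.2])

    def test_coincident_members_stay_finite(self):
        swarm = self._swarm([[0.5, 0.5], [0.5, 0.5]], [0.2, 0.4], [0.5, 0.5])
        cfg = GBSOConfig(N=2, it_max=100, jump_prob=0.0, seed=0)
        update_positions(swarm, cfg, np.random.default_rng(0))
        for g in swarm.members:
            assert np.all(np.isfinite(g.position))

    def test_two_member_hand_computation(self):
        """1-D pair at 0 and 1: the stated update moves member 0 to ~0.002235.

        d = 1 maps to d_hat = 3; s(3) = 0.5 e^-2 - e^-3 = 0.017881; with
        both members at the swarm mean the linear branch at it = it_max/2
        gives G = 0.500005, so x <- G*(G*0.5*s(3)*1) + 0.
        """
        swarm = self._swarm([[0.0], [1.0]], [0.5, 0.5], [0.0])
        cfg = GBSOConfig(N=2, it_max=100, jump_prob=0.0, seed=0)
        update_positions(swarm, cfg, np.random.default_rng(0),
                         avg_fitness=0.5)
        assert swarm.members[0].position[0] == pytest.approx(0.002235, abs=1e-6)

    def test_positions_clamped_to_bounds(self):
        rng = np.random.default_rng(0)
        swarm = self._swarm(rng.uniform(0, 1, size=(6, 4)).tolist(),
                            rng.uniform(0, 1, size=6).tolist(),
                            rng.uniform(0, 1, size=4).tolist())
        cfg = GBSOConfig(N=6, it_max=100, seed=0)
        for _ in range(5):
            update_positions(swarm, cfg, rng)
            for g in swarm.members:
                assert np.all((g.position >= 0) & (g.position <= 1))

    def test_unevaluated_fitness_rejected(self):
        swarm = Swarm(members=[Grasshopper(position=np.zeros(2))])
        with pytest.raises(RuntimeError):
            update_positions(swarm, GBSOConfig(seed=0), np.random.default_rng(0))


class TestSubsetFitness:
    def _separable(self, d=20, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X[y == 1, 0] += 10.0
        return LabeledDataset([(X[i], "ab"[y[i]]) for i in range(n)])

    def test_empty_mask_is_worst(self):
        ds = self._separable()
        assert subset_fitness(np.zeros(20, dtype=bool), ds,
                              GBSOConfig(seed=0)) == 1.0

    def test_single_perfect_feature(self):
        ds = self._separable()
        mask = np.zeros(20, dtype=bool)
        mask[0] = True
        fit = subset_fitness(mask, ds, GBSOConfig(seed=0))
        assert fit == pytest.approx((1 - 0.99) * (1 / 20), abs=1e-12)

    def test_permuted_labels_are_chance_level(self):
        fits = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 20))
            y = rng.permutation([0] * 100 + [1] * 100)
            ds = LabeledDataset([(X[i], "ab"[y[i]]) for i in range(200)])
            fits.append(subset_fitness(np.ones(20, dtype=bool), ds,
                                       GBSOConfig(seed=seed)))
        assert np.mean(fits) == pytest.approx(0.505, abs=0.05)

    def test_too_few_instances_per_class_rejected(self):
        rng = np.random.default_rng(0)
        ds = LabeledDataset([(rng.standard_normal(3), "a")] * 4 +
                            [(rng.standard_normal(3), "b")] * 4)
        with pytest.raises(ValueError):
            subset_fitness(np.ones(3, dtype=bool), ds, GBSOConfig(cv_folds=5, seed=0))


class TestSelection:
    def test_deterministic_given_seed(self):
        ds, _ = make_planted_features(n=60, d=8, seed=5)
        cfg = GBSOConfig(N=10, it_max=10, seed=5)
        a = gbso_select(ds, cfg)
        b = gbso_select(ds, cfg)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.fitness_history == b.fitness_history

    def test_history_non_increasing_and_mask_nonempty(self):
        ds, _ = make_planted_features(n=60, d=8, seed=3)
        res = gbso_select(ds, GBSOConfig(N=10, it_max=15, seed=3))
        assert res.mask.any()
        assert all(b <= a + 1e-12 for a, b in
                   zip(res.fitness_history, res.fitness_history[1:]))
        assert res.n_selected == int(res.mask.sum())

    def test_recovers_planted_features_single_run(self):
        ds, planted = make_planted_features(seed=1)
        res = gbso_select(ds, GBSOConfig(N=30, it_max=50, seed=1))
        sel = set(np.where(res.mask)[0])
        pl = set(np.where(planted)[0])
        assert len(sel & pl) / len(sel | pl) >= 0.5

    def test_selection_never_substantially_hurts(self):
        """With alpha = 1 the selected subset's wrapper error stays within
        0.05 of the full-feature wrapper error."""
        ds, _ = make_planted_features(seed=2)
        cfg = GBSOConfig(N=15, it_max=20, alpha=1.0, seed=2)
        res = gbso_select(ds, cfg)
        full_err = subset_fitness(np.ones(20, dtype=bool), ds, cfg)
        assert res.best_fitness <= full_err + 0.05

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        ds = LabeledDataset([(rng.standard_normal(4), "a") for _ in range(20)])
        with pytest.raises(ValueError):
            gbso_select(ds, GBSOConfig(seed=0))
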