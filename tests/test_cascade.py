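"""Cascade synapse dynamics: transition operators, invariants, and the
mean-field / finite-population correspondence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacascade import (CascadeParams, apply_isi, cascade_update, clear_boost,
                         effective_learning_rate, forgetting_step, init_cascade,
                         set_boost, simulate_finite_synapses, synaptic_strength)
from metacascade.cascade import mean_field_trajectory


class TestParams:
    def test_geometric_ladders(self):
        p = CascadeParams.geometric(0.5, 3, nr_shift=1)
        np.testing.assert_allclose(p.alpha_r, [0.5, 0.25, 0.125])
        np.testing.assert_allclose(p.alpha_nr, [0.25, 0.125, 0.0625])
        np.testing.assert_allclose(p.p_r, [0.5, 0.25])
        assert p.m == 3

    @pytest.mark.parametrize("kw", [
        dict(alpha_r=[0.5, 0.6], alpha_nr=[0.5, 0.25], p_r=[0.5], p_nr=[0.5]),
        dict(alpha_r=[0.5, 0.25], alpha_nr=[0.5, 0.25], p_r=[1.5], p_nr=[0.5]),
        dict(alpha_r=[0.5, 0.25], alpha_nr=[0.5, 0.25], p_r=[0.5], p_nr=[0.5],
             gamma=1.5),
    ])
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            CascadeParams(**{"gamma": 0.0, **kw})

    def test_single_rate_has_no_metaplasticity(self):
        p = CascadeParams.single(0.2)
        assert p.m == 1 and p.p_r.size == 0


class TestInit:
    def test_top_states_puts_half_mass_in_each_strength(self, ladder5):
        s = init_cascade(ladder5, 2, "top-states")
        assert s.f_plus[0, 0, 0] == 0.5 and s.f_minus[0, 1, 0] == 0.5
        assert s.f_plus[0, :, 1:].sum() == 0

    def test_uniform_fills_every_state(self, ladder5):
        s = init_cascade(ladder5, 2, "uniform")
        np.testing.assert_allclose(s.f_plus, 1 / 6)
        np.testing.assert_allclose(s.f_minus, 1 / 6)

    @pytest.mark.parametrize("mode", ["top-states", "uniform"])
    def test_unit_mass(self, ladder5, mode):
        s = init_cascade(ladder5, 3, mode)
        np.testing.assert_allclose(s.total_mass(), 1.0)

    def test_invalid_mode_rejected(self, ladder5):
        with pytest.raises(ValueError):
            init_cascade(ladder5, 2, "bottom")


class TestUpdate:
    def test_reward_flips_depressed_mass_to_top_potentiated(self):
        # all mass depressed at level 1; alpha_1 = 0.5 flips half of it
        p = CascadeParams.geometric(0.5, 2)
        s = init_cascade(p, 2)
        s.f_plus[..., :] = 0.0
        s.f_minus[0, :, 0] = 1.0
        out = cascade_update(s, 0, True, p)
        assert out.f_plus[0, 0, 0] == pytest.approx(0.5)
        assert out.f_minus[0, 0, 0] == pytest.approx(0.5)

    def test_deepest_potentiated_state_absorbs_on_congruent_outcome(self, ladder5):
        s = init_cascade(ladder5, 2)
        s.f_plus[..., :] = 0.0
        s.f_minus[..., :] = 0.0
        s.f_plus[0, 0, 2] = 1.0
        s.f_minus[0, 1, 0] = 1.0
        out = cascade_update(s, 0, True, ladder5)
        np.testing.assert_allclose(out.f_plus[0, 0], s.f_plus[0, 0])

    def test_gamma_zero_leaves_unchosen_population_untouched(self, ladder5, rng):
        s = init_cascade(ladder5, 2, "uniform")
        out = cascade_update(s, 0, True, ladder5)
        np.testing.assert_array_equal(out.f_plus[0, 1], s.f_plus[0, 1])
        np.testing.assert_array_equal(out.f_minus[0, 1], s.f_minus[0, 1])

    def test_gamma_scales_unchosen_opposite_update(self):
        p = CascadeParams.geometric(0.5, 3, gamma=1.0)
        s = init_cascade(p, 2, "uniform")
        out = cascade_update(s, 0, True, p)
        # unchosen population under reward receives the depression-direction
        # update at full scale: potentiated mass flips to top depressed state
        expect_minus_top = (1 / 6) * (1 - 0.5) + (1 / 6) * np.sum(p.alpha_r)
        assert out.f_minus[0, 1, 0] == pytest.approx(expect_minus_top)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.booleans()),
                    min_size=1, max_size=60),
           st.sampled_from([0.0, 0.3, 1.0]))
    def test_mass_conserved_under_any_update_sequence(self, seq, gamma):
        p = CascadeParams.geometric(0.3, 4, gamma=gamma)
        s = init_cascade(p, 2, "top-states")
        for choice, rewarded in seq:
            s = cascade_update(s, choice, rewarded, p)
        np.testing.assert_allclose(s.total_mass(), 1.0, atol=1e-12)
        assert np.all(s.f_plus >= 0) and np.all(s.f_minus >= 0)

    def test_monotone_consolidation_under_repeated_reward(self, ladder5):
        s = init_cascade(ladder5, 2)
        deep_prev = 0.0
        for _ in range(60):
            s = cascade_update(s, 0, True, ladder5)
            deep = s.f_plus[0, 0, 1:].sum()
            assert deep >= deep_prev - 1e-12
            deep_prev = deep


class TestForgetting:
    def test_potentiated_mass_decays_to_top_depressed(self, ladder5):
        s = init_cascade(ladder5, 2)
        s.f_plus[..., :] = 0.0
        s.f_minus[..., :] = 0.0
        s.f_plus[:, :, 1] = 1.0  # level 2, alpha_2 = 0.04
        out = forgetting_step(s, ladder5)
        assert out.f_plus[0, 0, 1] == pytest.approx(0.96)
        assert out.f_minus[0, 0, 0] == pytest.approx(0.04)

    def test_forgetting_conserves_mass_and_respects_symmetry(self, ladder5):
        s = init_cascade(ladder5, 2, "uniform")
        w0 = synaptic_strength(s, 0)
        out = forgetting_step(s, ladder5)
        np.testing.assert_allclose(out.total_mass(), 1.0, atol=1e-12)
        assert synaptic_strength(out, 0) == pytest.approx(w0)

    def test_repeated_forgetting_erases_strength_difference(self, ladder5):
        s = init_cascade(ladder5, 2)
        for _ in range(30):  # bias action 0 strongly
            s = cascade_update(s, 0, True, ladder5)
        w = s.f_plus.sum(axis=-1)
        gap0 = abs(w[0, 0] - w[0, 1])
        s = apply_isi(s, ladder5, n_units=10)
        w = s.f_plus.sum(axis=-1)
        assert abs(w[0, 0] - w[0, 1]) < 0.05 * gap0
        np.testing.assert_allclose(w, 0.5, atol=0.02)

    def test_isi_units_compose_and_contract(self, ladder5):
        s = init_cascade(ladder5, 2)
        for _ in range(30):
            s = cascade_update(s, 0, True, ladder5)
        same = apply_isi(s, ladder5, n_units=0)
        np.testing.assert_array_equal(same.f_plus, s.f_plus)
        one = apply_isi(s, ladder5, n_units=1)
        manual = s
        for _ in range(100):
            manual = forgetting_step(manual, ladder5)
        np.testing.assert_allclose(one.f_plus, manual.f_plus)
        five = apply_isi(s, ladder5, n_units=5)

        def dist(state):
            target = np.full_like(state.f_plus, 0.0)
            target[..., 0] = 0.5
            return (np.abs(state.f_plus - target).sum()
                    + np.abs(state.f_minus - target).sum())

        assert dist(five) < dist(one)


class TestBoost:
    def test_boost_elevates_shallow_rates_only(self, ladder5):
        s = init_cascade(ladder5, 2)
        s.f_plus[..., :] = 0.0
        s.f_minus[..., :] = 0.0
        s.f_minus[0, 0, 2] = 1.0  # deepest level, below the boost
        b = set_boost(s, 2)
        out = cascade_update(b, 0, True, ladder5)
        # level-3 rate unchanged: flips at alpha_3, not alpha_1
        assert out.f_plus[0, 0, 0] == pytest.approx(ladder5.alpha_r[2])

    def test_boost_applies_level_one_rate_within_reach(self, ladder5):
        s = init_cascade(ladder5, 2)
        s.f_plus[..., :] = 0.0
        s.f_minus[..., :] = 0.0
        s.f_minus[0, 0, 1] = 1.0
        out = cascade_update(set_boost(s, 2), 0, True, ladder5)
        assert out.f_plus[0, 0, 0] == pytest.approx(ladder5.alpha_r[0])

    def test_set_then_clear_restores_rates(self, ladder5):
        s = init_cascade(ladder5, 2)
        restored = clear_boost(set_boost(s, 3))
        assert not restored.boost.any()
        assert effective_learning_rate(restored, ladder5) == pytest.approx(
            effective_learning_rate(s, ladder5))

    def test_full_depth_boost_uses_top_rate_everywhere(self, ladder5):
        s = init_cascade(ladder5, 2, "uniform")
        b = set_boost(s, ladder5.m)
        assert effective_learning_rate(b, ladder5) == pytest.approx(
            ladder5.alpha_r[0])


class TestEffectiveRate:
    def test_point_mass_returns_level_rate(self, ladder5):
        s = init_cascade(ladder5, 2)  # all mass at level 1
        assert effective_learning_rate(s, ladder5) == pytest.approx(0.2)
        s.f_plus[..., :] = 0.0
        s.f_minus[..., :] = 0.0
        s.f_minus[:, :, 2] = 1.0
        assert effective_learning_rate(s, ladder5) == pytest.approx(
            ladder5.alpha_r[2])

    def test_weighted_mean_of_occupied_levels(self):
        p = CascadeParams.geometric(0.5, 2)
        s = init_cascade(p, 2)
        s.f_plus[..., :] = 0.0
        s.f_minus[..., :] = 0.0
        s.f_plus[:, :, 0] = 0.5
        s.f_minus[:, :, 1] = 0.5
        assert effective_learning_rate(s, p) == pytest.approx(0.375)

    def test_differing_ladders_use_per_level_mean(self):
        p = CascadeParams.geometric(0.5, 2, nr_shift=1)
        s = init_cascade(p, 2)  # all mass level 1
        assert effective_learning_rate(s, p) == pytest.approx((0.5 + 0.25) / 2)


class TestFiniteSynapseOracle:
    def test_single_synapse_occupancy_is_one_hot(self, ladder_half_m3):
        traj = simulate_finite_synapses(ladder_half_m3, 1,
                                        ["chosen_reward"] * 10, seed=0)
        assert np.all(traj.sum(axis=(1, 2)) == 1.0)
        assert np.all((traj == 0) | (traj == 1))

    def test_seeded_trajectories_are_reproducible(self, ladder_half_m3):
        ev = ["chosen_reward", "chosen_noreward", "forget"] * 5
        a = simulate_finite_synapses(ladder_half_m3, 500, ev, seed=7)
        b = simulate_finite_synapses(ladder_half_m3, 500, ev, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_mean_field_matches_stochastic_population(self):
        # 10^5 synapses over a mixed 200-trial event sequence: empirical
        # occupancies stay within 4 binomial SEs of the mean-field flow
        params = CascadeParams.geometric(0.2, 5, gamma=0.5)
        rng = np.random.default_rng(99)
        events = rng.choice(["chosen_reward", "chosen_noreward",
                             "unchosen_reward", "unchosen_noreward", "forget"],
                            size=200,
                            p=[0.35, 0.35, 0.1, 0.1, 0.1]).tolist()
        n = 100_000
        emp = simulate_finite_synapses(params, n, events, seed=11)
        mf = mean_field_trajectory(params, events)
        se = np.sqrt(mf * (1 - mf) / n)
        assert np.all(np.abs(emp - mf) <= 4 * se + 1e-12)
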