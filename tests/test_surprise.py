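"""Multi-timescale reward monitors, expected uncertainty, and surprise tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metacascade import (CascadeParams, MonitorBank, SurpriseParams,
                         detect_surprise, monitor_update, step_surprise_system,
                         uncertainty_update)


def make_bank(alphas=(0.2, 0.04, 0.008), n_runs=1, calibrated=True):
    m = len(alphas)
    params = CascadeParams(alpha_r=np.asarray(alphas),
                           alpha_nr=np.asarray(alphas),
                           p_r=np.asarray(alphas[:-1]),
                           p_nr=np.asarray(alphas[:-1]))
    bank = MonitorBank.from_cascade(params, n_runs=n_runs)
    if calibrated:
        bank.trials_seen = 10 ** 9
    return bank


class TestMonitorUpdate:
    def test_reward_moves_depressed_mass_up(self):
        bank = make_bank()
        bank.g_plus[:] = 0.0
        out = monitor_update(bank, True)
        np.testing.assert_allclose(out.g_plus[0], [0.2, 0.04, 0.008])

    def test_noreward_moves_potentiated_mass_down(self):
        bank = make_bank((0.2, 0.04))
        bank.g_plus[:] = 1.0
        out = monitor_update(bank, False)
        np.testing.assert_allclose(out.g_plus[0], [0.8, 0.96])

    def test_iid_rewards_drive_readout_to_reward_rate(self):
        bank = make_bank((0.5, 0.1, 0.02))
        rng = np.random.default_rng(8)
        r = 0.3
        tail = []
        for t in range(10_000):
            bank = monitor_update(bank, bool(rng.random() < r))
            if t > 8000:
                tail.append(bank.g_plus[0].copy())
        np.testing.assert_allclose(np.mean(tail, axis=0), r, atol=0.05)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_readout_bounded_for_any_reward_sequence(self, rewards):
        bank = make_bank()
        for r in rewards:
            bank = monitor_update(bank, r)
        assert np.all(bank.g_plus >= 0) and np.all(bank.g_plus <= 1)

    def test_relaxation_after_step_change_is_geometric(self):
        # deterministic mean dynamics: |G - r_new| shrinks by (1-alpha)/trial
        bank = make_bank((0.2,) )
        bank.g_plus[:] = 0.9
        gaps = []
        for _ in range(10):
            bank = monitor_update(bank, False)  # new rate 0
            gaps.append(bank.g_plus[0, 0])
        np.testing.assert_allclose(gaps, 0.9 * 0.8 ** np.arange(1, 11))


class TestUncertainty:
    def test_fixed_point_at_current_discrepancy(self):
        bank = make_bank((0.2, 0.04))
        bank.g_plus[0] = [0.6, 0.4]
        bank.u[0, 0] = 0.2
        out = uncertainty_update(bank)
        assert out.u[0, 0] == pytest.approx(0.2)

    def test_learning_uses_slower_rate_of_the_pair(self):
        bank = make_bank((0.2, 0.04))
        bank.g_plus[0] = [0.6, 0.4]
        out = uncertainty_update(bank)
        assert out.u[0, 0] == pytest.approx(0.04 * 0.2)

    def test_geometric_approach_to_constant_discrepancy(self):
        bank = make_bank((0.2, 0.04))
        bank.g_plus[0] = [0.7, 0.5]
        us = []
        for _ in range(50):
            bank = uncertainty_update(bank)
            us.append(bank.u[0, 0])
        expect = 0.2 * (1 - (1 - 0.04) ** np.arange(1, 51))
        np.testing.assert_allclose(us, expect, rtol=1e-10)

    def test_expected_uncertainty_is_convex_combination_of_history(self):
        rng = np.random.default_rng(1)
        bank = make_bank((0.2, 0.04))
        hist = []
        for _ in range(300):
            bank.g_plus[0] = rng.random(2)
            hist.append(abs(bank.g_plus[0, 0] - bank.g_plus[0, 1]))
            bank = uncertainty_update(bank)
        assert 0 <= bank.u[0, 0] <= max(hist)


class TestDetection:
    def test_equal_readouts_never_fire(self):
        bank = make_bank()
        bank.g_plus[:] = 0.4
        bank.u[:] = 0.05
        surprise, level, fired = detect_surprise(bank, SurpriseParams(h=0.05))
        assert not surprise.any() and level[0] == 0

    def test_rising_reward_rate_never_fires(self):
        # fast readout far above slow: improvement, not a surprise
        bank = make_bank()
        bank.g_plus[0] = [0.9, 0.2, 0.2]
        bank.u[:] = 1e-4
        surprise, _, _ = detect_surprise(bank, SurpriseParams(h=0.05))
        assert not surprise.any()

    def test_large_drop_relative_to_expectation_fires(self):
        bank = make_bank()
        bank.g_plus[0] = [0.2, 0.5, 0.5]   # fast fell 0.3 below slow
        bank.u[:] = 0.01
        surprise, level, fired = detect_surprise(bank, SurpriseParams(h=0.05))
        assert surprise[0]
        # boost reaches the slow level of the deepest firing pair
        assert level[0] == 3

    def test_uncalibrated_pairs_do_not_fire(self):
        bank = make_bank(calibrated=False)
        bank.g_plus[0] = [0.2, 0.5, 0.5]
        bank.u[:] = 0.01
        surprise, _, _ = detect_surprise(bank, SurpriseParams(h=0.05))
        assert not surprise.any()
        bank.trials_seen = int(2 / 0.04)  # pair (1,2) calibrated, others not
        _, level, fired = detect_surprise(bank, SurpriseParams(h=0.05))
        assert level[0] == 2

    def test_zero_uncertainty_handled_by_floor(self):
        bank = make_bank()
        bank.g_plus[0] = [0.4, 0.41, 0.41]
        bank.u[:] = 0.0
        surprise, _, _ = detect_surprise(bank, SurpriseParams(h=0.05))
        assert surprise[0]  # any deficit is infinitely surprising at u=0

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            SurpriseParams(h=0.7)


class TestClosedLoop:
    def test_no_surprise_when_fast_estimates_exceed_slow(self):
        # improvement-only sequence: monitors start at 0 and rewards are
        # certain, so every faster readout stays above every slower one
        bank = make_bank((0.5, 0.1, 0.02))
        bank.g_plus[:] = 0.0
        bank.trials_seen = 10 ** 9
        fired_any = False
        params = SurpriseParams(h=0.05)
        for _ in range(500):
            bank, level = step_surprise_system(bank, True, params)
            fired_any |= bool(level[0] > 0)
        assert not fired_any

    def test_step_drop_detected_then_released(self):
        # the d/u ratio test is scale-free, so the stable false-alarm rate is
        # set by h alone (one-sided tail of ~N(0, 1/0.8) per pair); h=0.005
        # keeps the per-trial union under ~10% while a step drop of 0.6 in
        # reward rate is detected essentially always
        rng = np.random.default_rng(4)
        bank = make_bank((0.5, 0.1, 0.02), n_runs=200)
        params = SurpriseParams(h=0.005)
        for t in range(500):
            bank, level = step_surprise_system(
                bank, rng.random(200) < 0.8, params)
        burn_levels = []
        for t in range(200):
            bank, level = step_surprise_system(
                bank, rng.random(200) < 0.8, params)
            burn_levels.append((level > 0).mean())
        assert np.mean(burn_levels) < 0.1  # quiet in the stable regime
        hit = np.zeros(200, dtype=bool)
        post = []
        for t in range(150):
            bank, level = step_surprise_system(
                bank, rng.random(200) < 0.2, params)
            if t < 50:
                hit |= level > 0
            post.append((level > 0).mean())
        assert hit.mean() > 0.9  # drop 0.8 -> 0.2 is caught within 50 trials
        # expected uncertainty catches up and the signal is released
        assert np.mean(post[-20:]) < 0.5 * np.max(post)
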