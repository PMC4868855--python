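"""Phase construction, circular statistics and outcome measures."""

import math

import numpy as np
import pytest

from crstim import analysis as an


class TestPhases:
    def test_linear_interpolation_between_spikes(self):
        trains = [np.array([0.0, 10.0, 20.0])]
        ph = an.phases_at(trains, np.array([0.0, 2.5, 5.0, 7.5, 15.0]))
        np.testing.assert_allclose(
            ph[0], [0.0, np.pi / 2, np.pi, 3 * np.pi / 2, np.pi]
        )

    def test_undefined_outside_first_last_spike(self):
        trains = [np.array([5.0, 15.0])]
        ph = an.phases_at(trains, np.array([0.0, 5.0, 14.9, 15.0, 20.0]))
        assert np.isnan(ph[0, 0])
        assert ph[0, 1] == 0.0
        assert np.isnan(ph[0, 3])  # phase defined on [first, last)
        assert np.isnan(ph[0, 4])


class TestAverageWeight:
    def test_zero_weights(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert an.average_weight(np.zeros((2, 2)), m) == 0.0

    def test_two_neuron_toy(self):
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        c = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert an.average_weight(c, m) == pytest.approx(0.25)

    def test_balanced_signs_cancel(self):
        m = np.array([[0.0, 1.0], [-1.0, 0.0]])
        c = np.array([[0.0, 0.3], [0.3, 0.0]])
        assert an.average_weight(c, m) == pytest.approx(0.0)


class TestOrderParameter:
    def test_perfect_synchrony(self):
        r, phi = an.order_parameter(np.full(50, 1.3))
        assert r == pytest.approx(1.0)
        assert phi == pytest.approx(1.3)

    def test_symmetric_cancellation(self):
        r, _ = an.order_parameter(np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]))
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_two_phase_closed_form(self):
        r, _ = an.order_parameter(np.array([0.0, np.pi / 2]))
        assert r == pytest.approx(math.sqrt(2) / 2)

    def test_undefined_fraction_guard(self):
        phases = np.full(10, 0.5)
        phases[:2] = np.nan  # 20% undefined
        with pytest.raises(ValueError):
            an.order_parameter(phases)

    def test_small_undefined_fraction_excluded(self):
        phases = np.full(20, 0.7)
        phases[0] = np.nan  # 5% undefined: excluded, not fatal
        r, _ = an.order_parameter(phases)
        assert r == pytest.approx(1.0)


class TestSubgroups:
    def test_partition(self):
        g = an.SubgroupDef(200, 4)
        np.testing.assert_array_equal(g.indices(0), np.arange(0, 50))
        np.testing.assert_array_equal(g.indices(3), np.arange(150, 200))
        with pytest.raises(ValueError):
            an.SubgroupDef(10, 4)

    def test_synced_subgroup_in_noisy_population(self, rng):
        phases = rng.uniform(0, 2 * np.pi, 200)
        phases[:50] = 2.0
        g = an.SubgroupDef(200, 4)
        r_sg, phi_sg = an.subgroup_order_parameter(phases, 0, g)
        r_all, _ = an.order_parameter(phases)
        assert r_sg == pytest.approx(1.0)
        assert phi_sg == pytest.approx(2.0)
        assert r_all < 0.5

    def test_degenerate_single_group_equals_population(self, rng):
        phases = rng.uniform(0, 2 * np.pi, 12)
        g = an.SubgroupDef(12, 1)
        np.testing.assert_allclose(
            an.subgroup_order_parameter(phases, 0, g),
            an.order_parameter(phases),
        )

    def test_hand_built_complex_mean(self):
        phases = np.array([0.1, 1.0, 2.0, 3.0])
        g = an.SubgroupDef(4, 1)
        r, phi = an.subgroup_order_parameter(phases, 0, g)
        z = np.mean(np.exp(1j * phases))
        assert r == pytest.approx(abs(z))
        assert phi == pytest.approx(np.angle(z) % (2 * np.pi))


class TestCrossTrial:
    def test_periodic_entrainment_degenerate_distribution(self):
        period = 16.0

        def phi_fn(times):
            return (2 * np.pi * np.asarray(times) / period) % (2 * np.pi)

        onsets = np.arange(100.0, 1000.0, period)
        lags, mat = an.cross_trial_phases(phi_fn, onsets, (-32, 32), 1.0)
        assert mat.shape == (onsets.size, 65)
        # all trials identical at each lag -> E = 1 everywhere
        np.testing.assert_allclose(an.resetting_index(mat), 1.0)

    def test_uniform_phases_give_low_index(self, rng):
        def phi_fn(times):
            return rng.uniform(0, 2 * np.pi, np.size(times))

        onsets = np.arange(0.0, 4000.0, 16.0)
        _, mat = an.cross_trial_phases(phi_fn, onsets, (-32, 32), 1.0)
        e = an.resetting_index(mat)
        assert e.max() < 0.25  # ~1/sqrt(250) scale fluctuations

    def test_out_of_record_onsets_dropped(self):
        def phi_fn(times):
            return np.zeros(np.size(times))

        onsets = np.array([10.0, 500.0, 990.0])
        _, mat = an.cross_trial_phases(
            phi_fn, onsets, (-32, 32), 1.0, t_valid=(0.0, 1000.0)
        )
        assert mat.shape[0] == 1  # only the middle onset fits the window


class TestResettingIndex:
    @pytest.mark.parametrize(
        "phases, expected",
        [
            (np.full(8, 2.2), 1.0),
            (np.arange(8) * 2 * np.pi / 8, 0.0),
            (np.array([0.0, 0.0, np.pi, np.pi]), 0.0),
            (np.array([0.0, 0.0, 0.0, np.pi]), 0.5),
        ],
    )
    def test_complex_sum_examples(self, phases, expected):
        assert an.resetting_index(phases) == pytest.approx(expected, abs=1e-12)


class TestAcuteEffects:
    def test_no_effect(self):
        assert an.acute_effects(0.9, 0.9, 0.9) == pytest.approx((0.0, 0.0))

    def test_full_desynchronization(self):
        acute, after = an.acute_effects(0.9, 0.0, 0.9)
        assert acute == pytest.approx(1.0)

    def test_half_reduction(self):
        acute, _ = an.acute_effects(0.9, 0.45, 0.9)
        assert acute == pytest.approx(0.5)

    def test_zero_baseline_flagged(self):
        with pytest.raises(ValueError):
            an.acute_effects(0.0, 0.5, 0.5)


class TestPhaseDifferences:
    def test_identical_series_single_bin(self):
        phi = np.linspace(0, 2 * np.pi, 1000) % (2 * np.pi)
        theta = an.phase_difference_series(phi, phi)
        edges, counts = an.phase_difference_histogram(theta)
        assert counts.sum() == 1000
        assert (counts > 0).sum() == 1
        assert edges.size - 1 == 36  # pi/18 bins over [0, 2pi)

    def test_constant_offset_atom(self):
        phi = np.linspace(0, 2 * np.pi, 500)
        theta = an.phase_difference_series(phi + np.pi / 2, phi)
        np.testing.assert_allclose(theta, np.pi / 2, atol=1e-12)

    def test_sample_count_ten_second_window(self):
        times = np.arange(0.0, 10000.0, 1.0)
        phi_j = (0.1 * times) % (2 * np.pi)
        phi_k = (0.1 * times + 1.0) % (2 * np.pi)
        theta = an.phase_difference_series(phi_j, phi_k)
        assert theta.size == 10000

    def test_undefined_samples_dropped(self):
        phi_j = np.array([0.0, np.nan, 1.0])
        phi_k = np.array([0.5, 0.5, np.nan])
        assert an.phase_difference_series(phi_j, phi_k).size == 1


class TestLambdaAlpha:
    def test_constant_difference_all_orders(self):
        theta = np.full(100, 1.234)
        for nu in (1, 2, 3, 4):
            assert an.lambda_index(theta, nu) == pytest.approx(1.0)
        assert an.alpha_index(theta) == 0.0

    def test_uniform_grid_vanishes(self):
        theta = np.arange(3600) * 2 * np.pi / 3600
        for nu in (1, 2, 3, 4):
            assert an.lambda_index(theta, nu) == pytest.approx(0.0, abs=1e-12)

    def test_three_peak_atoms(self):
        theta = np.repeat([3 * np.pi / 2, 0.0, np.pi / 2], 100)
        assert an.lambda_index(theta, 1) == pytest.approx(1.0 / 3.0)
        assert an.lambda_index(theta, 4) == pytest.approx(1.0)
        assert an.alpha_index(theta) == pytest.approx(2.0 / 3.0)

    def test_four_peak_atoms(self):
        theta = np.repeat([-np.pi / 2, 0.0, np.pi / 2, np.pi], 50)
        assert an.lambda_index(theta, 1) == pytest.approx(0.0, abs=1e-14)
        assert an.alpha_index(theta) == pytest.approx(1.0)

    def test_kernels_match_bruteforce_complex_sums(self):
        """lambda/alpha and E agree with a literal complex-sum loop, 1000 multisets."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            theta = rng.uniform(0, 2 * np.pi, rng.integers(1, 40))
            for nu in (1, 4):
                z = complex(0.0)
                for x in theta:
                    z += complex(math.cos(nu * x), math.sin(nu * x))
                ref = abs(z) / theta.size
                assert abs(an.lambda_index(theta, nu) - ref) < 1e-12
            # resetting index is the nu=1 kernel applied to a phase multiset
            assert abs(
                an.resetting_index(theta) - an.lambda_index(theta, 1)
            ) < 1e-12


class TestMannWhitney:
    def test_identical_groups_not_significant(self):
        a = np.arange(11, dtype=float)
        _, p = an.mann_whitney_one_sided(a, a.copy())
        assert 0.4 < p < 0.6

    def test_complete_separation_exact_p(self):
        a = np.arange(11, dtype=float)
        b = a + 100.0
        u, p = an.mann_whitney_one_sided(a, b)
        assert u == 0.0
        assert p == pytest.approx(1.0 / math.comb(22, 11), rel=1e-9)

    def test_swap_duality(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 9)
        _, p_ab = an.mann_whitney_one_sided(a, b)
        _, p_ba = an.mann_whitney_one_sided(b, a)
        assert p_ab + p_ba >= 1.0 - 1e-12
        assert abs(p_ab - (1.0 - p_ba)) < 0.05  # off by the point mass at U_obs

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            an.mann_whitney_one_sided([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBoxplotStats:
    def test_degenerate_values(self):
        stats = an.boxplot_stats(np.full(11, 3.3))
        assert stats["median"] == stats["q1"] == stats["q3"] == 3.3
        assert stats["outliers"].size == 0

    def test_one_to_eleven(self):
        stats = an.boxplot_stats(np.arange(1.0, 12.0))
        assert stats["median"] == 6.0
        assert stats["q1"] == pytest.approx(3.5)
        assert stats["q3"] == pytest.approx(8.5)
        assert stats["outliers"].size == 0
        assert stats["whisker_low"] == 1.0 and stats["whisker_high"] == 11.0

    def test_outlier_flagged(self):
        vals = list(range(1, 11)) + [100]
        stats = an.boxplot_stats(vals)
        np.testing.assert_array_equal(stats["outliers"], [100.0])
        assert stats["whisker_high"] == 10.0


def test_mean_order_parameter_tolerates_trailing_gap():
    # two neurons spiking regularly, record ends at 100 ms
    trains = [np.arange(0.0, 101.0, 10.0), np.arange(0.5, 101.0, 10.0)]
    r = an.mean_order_parameter(trains, 0.0, 105.0)
    assert 0.9 < r <= 1.0
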