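"""Winner-take-all selection statistic: calibration, oracles, conditioned variants."""
import numpy as np
import pytest
from scipy import stats

import lamsel as L
from conftest import exact_win_probability
from lamsel.errors import ConfigurationError, WindowError
from lamsel.reliability import ResponsePool, SelectionResult

CHANCE = 100.0 / 6.0


def _binom_sd(p, n):
    return 100.0 * np.sqrt(p * (1 - p) / n)


class TestSimulateSelection:
    def test_dominant_oddball_selected_always(self):
        pool = ResponsePool(np.ones((3, 5)), np.zeros((4, 5)))
        res = L.simulate_selection(pool, pop_sizes=(1, 3), n_sims=200, seed=0)
        assert (res.freq == 100.0).all()

    def test_identical_pool_for_all_alternatives_sits_at_chance(self):
        # exchangeability: every alternative draws from the same pool
        rng = np.random.default_rng(0)
        shared = rng.normal(size=(200, 8))
        pool = ResponsePool(shared, shared)
        res = L.simulate_selection(pool, pop_sizes=(1, 49), n_sims=1000, seed=1)
        tol = 3 * _binom_sd(1 / 6, 1000)
        assert np.abs(res.freq - CHANCE).max() < tol

    @pytest.mark.parametrize("odd,dist,pop", [
        ([2.0], [1.0, 3.0], 1),
        ([2.0], [1.0, 3.0], 2),
        ([1.0, 2.0, 4.0], [0.0, 3.0, 3.0], 2),
        ([1.0, 1.0], [1.0, 2.0], 1),  # exercises tie splitting
    ])
    def test_monte_carlo_matches_enumeration(self, odd, dist, pop):
        expected = exact_win_probability(odd, dist, 6, pop)
        pool = ResponsePool(np.array(odd)[:, None], np.array(dist)[:, None])
        res = L.simulate_selection(pool, pop_sizes=(pop,), n_sims=2000, seed=2)
        tol = max(3 * _binom_sd(expected / 100.0, 2000), 0.2)
        assert res.freq[0, 0] == pytest.approx(expected, abs=tol)

    def test_winner_frequencies_sum_to_hundred(self):
        rng = np.random.default_rng(3)
        pool = ResponsePool(rng.normal(size=(20, 6)), rng.normal(size=(50, 6)))
        res = L.simulate_selection(pool, pop_sizes=(1, 9), n_sims=300, seed=4,
                                   keep_all=True)
        np.testing.assert_allclose(res.freq_all.sum(axis=0), 100.0, atol=1e-9)

    def test_positive_shift_never_decreases_selection(self):
        rng = np.random.default_rng(5)
        base_odd = rng.normal(size=(50, 1))
        dist = rng.normal(size=(200, 1))
        f0 = L.simulate_selection(ResponsePool(base_odd, dist), pop_sizes=(9,),
                                  n_sims=10_000, seed=6).freq[0, 0]
        f1 = L.simulate_selection(ResponsePool(base_odd + 1.0, dist), pop_sizes=(9,),
                                  n_sims=10_000, seed=7).freq[0, 0]
        assert f1 > f0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        pool = ResponsePool(rng.normal(size=(10, 4)), rng.normal(size=(30, 4)))
        a = L.simulate_selection(pool, n_sims=200, seed=42)
        b = L.simulate_selection(pool, n_sims=200, seed=42)
        np.testing.assert_array_equal(a.freq, b.freq)

    def test_empty_pool_rejected(self):
        with pytest.raises(ConfigurationError):
            ResponsePool(np.empty((0, 4)), np.ones((3, 4)))


class TestChanceWindow:
    def _pool(self, odd_shift=0.0, seed=0, t=30):
        rng = np.random.default_rng(seed)
        time_ms = np.arange(-float(t), 10.0)
        return ResponsePool(rng.normal(size=(40, time_ms.size)) + odd_shift,
                            rng.normal(size=(200, time_ms.size)),
                            time_ms=time_ms), time_ms

    def test_brackets_chance_for_exchangeable_pools(self):
        pool, t = self._pool()
        lo, hi = L.chance_window(pool, t < 0, pop_sizes=(1, 49, 250),
                                 n_sims=500, seed=1)
        assert lo < CHANCE < hi

    def test_biased_oddball_shifts_window_up(self):
        pool, t = self._pool(odd_shift=10.0)
        lo, hi = L.chance_window(pool, t < 0, pop_sizes=(49, 250),
                                 n_sims=500, seed=2)
        assert lo > CHANCE

    def test_window_widens_with_fewer_simulations(self):
        pool, t = self._pool(seed=3)
        lo1, hi1 = L.chance_window(pool, t < 0, pop_sizes=(49,), n_sims=1000, seed=4)
        lo2, hi2 = L.chance_window(pool, t < 0, pop_sizes=(49,), n_sims=100, seed=4)
        assert (hi2 - lo2) > (hi1 - lo1)

    def test_short_baseline_rejected(self):
        pool, t = self._pool()
        with pytest.raises(WindowError):
            L.chance_window(pool, t < -25)


class TestSelectionTime:
    def _result(self, freq_trace, pop=250):
        t = np.arange(-20.0, float(freq_trace.size) - 20.0)
        return SelectionResult(freq=freq_trace[:, None], pop_sizes=(pop,),
                               n_sims=1000, n_items=6, time_ms=t,
                               chance_window=(14.0, 19.0))

    def test_flat_chance_trace_never_crosses(self):
        res = self._result(np.full(120, CHANCE))
        assert L.selection_time(res)[250] is None

    def test_sustained_step_detected_at_onset(self):
        freq = np.full(150, CHANCE)
        freq[80:130] = 90.0  # step at t = 60 ms lasting 50 ms
        res = self._result(freq)
        assert L.selection_time(res)[250] == pytest.approx(60.0)

    def test_single_sample_blip_ignored(self):
        freq = np.full(150, CHANCE)
        freq[80] = 90.0
        res = self._result(freq)
        assert L.selection_time(res)[250] is None


class TestDepthResolved:
    def test_uniform_pools_at_chance_everywhere(self):
        rng = np.random.default_rng(0)
        pools = {}
        for d in range(4):
            shared = rng.normal(size=(60, 3))
            pools[d] = ResponsePool(shared, shared)
        out = L.depth_resolved_selection(pools, pop_sizes=(49,), n_sims=800, seed=1)
        for res in out.values():
            assert np.abs(res.freq - CHANCE).max() < 3 * _binom_sd(1 / 6, 800)

    def test_missing_depth_marked_none(self):
        rng = np.random.default_rng(1)
        pools = {0: ResponsePool(rng.normal(size=(10, 2)), rng.normal(size=(20, 2))),
                 1: None}
        out = L.depth_resolved_selection(pools, pop_sizes=(9,), n_sims=100)
        assert out[1] is None and out[0] is not None

    def test_permuting_depth_labels_permutes_outputs(self):
        rng = np.random.default_rng(2)
        pools = {d: ResponsePool(rng.normal(size=(15, 3)) + d,
                                 rng.normal(size=(40, 3))) for d in range(3)}
        fwd = L.depth_resolved_selection(pools, pop_sizes=(9,), n_sims=300, seed=5)
        rev = L.depth_resolved_selection(dict(reversed(pools.items())),
                                         pop_sizes=(9,), n_sims=300, seed=5)
        for d in pools:
            np.testing.assert_array_equal(fwd[d].freq, rev[d].freq)


class TestWithinTrial:
    def test_single_column_dominance_is_total(self):
        pool = ResponsePool(np.ones((5, 4)) * 3.0, np.zeros((5, 4)))
        res = L.within_trial_selection(pool, n_sims=300, seed=0)
        assert (res.freq == 100.0).all()

    def test_matches_pseudo_population_for_independent_units(self):
        # column-trial sums of m iid units vs m independent pseudo-population draws
        rng = np.random.default_rng(3)
        m, n_tr, t = 8, 300, 3
        odd_units = rng.normal(0.4, 1.0, size=(n_tr * m, t))
        dist_units = rng.normal(0.0, 1.0, size=(n_tr * m, t))
        odd_cols = odd_units.reshape(n_tr, m, t).sum(axis=1)
        dist_cols = dist_units.reshape(n_tr, m, t).sum(axis=1)
        wt = L.within_trial_selection(ResponsePool(odd_cols, dist_cols),
                                      n_sims=2000, seed=4).freq[:, 0]
        pseudo = L.simulate_selection(ResponsePool(odd_units, dist_units),
                                      pop_sizes=(m,), n_sims=2000, seed=5).freq[:, 0]
        assert np.abs(wt - pseudo).max() < 5.0  # two Monte-Carlo estimates


class TestErrorTrials:
    def _pools(self, odd_level, dist_level, seed=0):
        # baseline is exactly zero so the pre-stimulus epoch is pure tie-break
        rng = np.random.default_rng(seed)
        t = np.arange(-20.0, 40.0)
        odd = np.zeros((60, t.size))
        dist = np.zeros((120, t.size))
        odd[:, t >= 0] = rng.normal(odd_level, 1.0, size=(60, (t >= 0).sum()))
        dist[:, t >= 0] = rng.normal(dist_level, 1.0, size=(120, (t >= 0).sum()))
        return ResponsePool(odd, dist, time_ms=t), t

    def test_distractor_boost_drives_signed_metric_negative(self):
        pool, t = self._pools(0.0, 1.5)
        res = L.error_trial_selection(pool, pop_sizes=(49,), n_sims=600, seed=1)
        assert res.selection_vs_chance[t >= 5, 0].mean() < -5.0

    def test_correct_trials_drive_signed_metric_positive(self):
        pool, t = self._pools(1.5, 0.0)
        res = L.error_trial_selection(pool, pop_sizes=(49,), n_sims=600, seed=2)
        assert res.selection_vs_chance[t >= 5, 0].mean() > 5.0

    def test_baseline_epoch_stays_near_chance(self):
        pool, t = self._pools(0.0, 1.5)
        res = L.error_trial_selection(pool, pop_sizes=(49,), n_sims=600, seed=3)
        assert np.abs(res.selection_vs_chance[t < 0, 0]).max() < \
            3 * _binom_sd(1 / 6, 600) + 1.0


class TestBaselineBias:
    def test_analytic_t_statistic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(16.67, 1.0, 100)
        b = rng.normal(18.67, 1.0, 100)
        res = L.baseline_bias(a, b)
        assert abs(res.t_stat) == pytest.approx(14.0, abs=3.0)
        assert res.p_value < 1e-10

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(1)
        res = L.baseline_bias(rng.normal(16.67, 1.0, 500),
                              rng.normal(16.67, 1.0, 500))
        assert res.p_value > 0.05

    def test_constant_group_gives_finite_t(self):
        res = L.baseline_bias(np.full(50, 16.0), np.random.default_rng(2)
                              .normal(17.0, 1.0, 50))
        assert np.isfinite(res.t_stat)

    def test_simulated_baseline_frequencies_near_chance(self):
        rng = np.random.default_rng(3)
        t = np.arange(-50.0, 10.0)
        shared = rng.normal(size=(150, t.size))
        pool = ResponsePool(shared, shared, time_ms=t)
        freqs = L.baseline_selection_frequencies(pool, t < 0, pop_size=49,
                                                 n_sims=400, seed=4)
        assert freqs.shape == (400,)
        assert abs(freqs.mean() - CHANCE) < 2.0


class TestFeatureSelectivity:
    def test_uniform_dominance_is_total(self):
        green = np.random.default_rng(0).normal(size=500)
        assert L.feature_selectivity(green + 1.0, green, seed=1) == 100.0

    def test_identical_distributions_unselective(self):
        x = np.random.default_rng(1).normal(size=500)
        pref = L.feature_selectivity(x, x.copy(), seed=2)
        assert pref == pytest.approx(50.0, abs=3 * 1.58 + 1.0)

    def test_matches_gaussian_closed_form_conditioned_on_pool(self):
        rng = np.random.default_rng(2)
        red = rng.normal(1.0, 1.0, 2000)
        green = rng.normal(0.9, 1.0, 2000)
        n = 100
        mu = n * (red.mean() - green.mean())
        sd = np.sqrt(n * (red.var() + green.var()))
        expected = 100.0 * stats.norm.cdf(mu / sd)
        got = L.feature_selectivity(red, green, n_draw=n, n_sims=1000, seed=3)
        assert got == pytest.approx(expected, abs=3 * _binom_sd(expected / 100, 1000))


class TestAdjacency:
    def test_suppressed_adjacent_distractors_raise_selection(self):
        rng = np.random.default_rng(0)
        t = 4
        odd = rng.normal(1.0, 1.0, size=(60, t))
        adj = rng.normal(-0.5, 1.0, size=(120, t))   # suppressed
        opp = rng.normal(1.0, 1.0, size=(120, t))
        out = L.adjacency_conditioned_selection(
            {"adjacent": ResponsePool(odd, adj), "opposite": ResponsePool(odd, opp)},
            pop_sizes=(9,), n_sims=800, seed=1)
        assert out["adjacent"].freq.mean() > out["opposite"].freq.mean() + 10.0

    def test_identical_pools_give_identical_results_up_to_mc_error(self):
        rng = np.random.default_rng(1)
        odd = rng.normal(0.5, 1.0, size=(50, 3))
        dist = rng.normal(size=(150, 3))
        out = L.adjacency_conditioned_selection(
            {"a": ResponsePool(odd, dist), "b": ResponsePool(odd, dist)},
            pop_sizes=(9,), n_sims=1500, seed=2)
        assert np.abs(out["a"].freq - out["b"].freq).max() < 6.0

    def test_empty_geometry_mapping_rejected(self):
        with pytest.raises(ConfigurationError):
            L.adjacency_conditioned_selection({})


def test_pools_from_session_counts_and_nan_exclusion():
    x = np.arange(2 * 3 * 4, dtype=float).reshape(2, 3, 4)
    x[0, 1, 2] = np.nan
    odd = np.array([True, False, True, False])
    dist = ~odd
    pool = L.pools_from_session(x, odd, dist)
    assert pool.oddball.shape == (3, 3)      # NaN channel-trial (ch 0, trial 2) dropped
    assert pool.distractor.shape == (4, 3)   # 2 channels x 2 trials intact
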