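"""Tuning curves, shuffle test, place-field metrics, decoder, statistics."""

import numpy as np
import pytest
from scipy import stats

import looptrack.analysis as ana
from looptrack.analysis import (
    BayesDecoder,
    EventTrain,
    OccupancyMap,
    TuningCurve,
    binarize_events,
    chance_by_label_shuffle,
    chance_level_circular,
    compute_occupancy,
    compute_tuning,
    decode_posterior,
    decoding_error,
    detect_place_fields,
    fit_decoder,
    optimal_circular_shift,
    per_lap_event_bins,
    rate_map_correlation,
    select_significant_transients,
    sensitivity,
    shuffle_threshold,
    spatial_information,
    specificity,
    two_proportion_ztest,
)

L = 2000.0
B = 50


def uniform_train(amplitudes, n_laps=4):
    """Event train on a constant-speed trace (uniform occupancy)."""
    n = len(amplitudes)
    pos = (np.arange(n) / n * n_laps * L) % L
    lap = (np.arange(n) / n * n_laps).astype(int)
    return EventTrain(amplitudes=amplitudes, frame_period_s=1 / 30.0,
                      position_mm=pos, lap=lap)


class TestBinarization:
    def test_all_zero_train_stays_zero(self):
        raw = np.sin(np.linspace(0, 10, 100))
        out = binarize_events(np.zeros(100), raw)
        assert not out.any()

    def test_threshold_is_median_plus_4_unscaled_mads(self):
        raw = np.array([0.0, 1.0, 2.0, 3.0, 4.0] * 20)  # median 2, MAD 1
        amps = np.zeros(100)
        amps[:3] = [0.0, 1.0, 10.0]
        out = binarize_events(amps, raw)  # threshold = 2 + 4*1 = 6
        assert list(out[:3]) == [0.0, 0.0, 10.0]

    def test_known_above_below_counts(self):
        rng = np.random.default_rng(3)
        raw = rng.normal(0, 1, 5000)
        amps = rng.uniform(0, 8, 5000)
        thr = np.median(raw) + 4 * np.median(np.abs(raw - np.median(raw)))
        expected = int((amps > thr).sum())
        assert int((binarize_events(amps, raw) > 0).sum()) == expected

    def test_constant_raw_trace_warns_and_keeps_nonzero(self):
        with pytest.warns(UserWarning):
            out = binarize_events(np.array([0.0, 2.0]), np.ones(2))
        assert list(out) == [0.0, 2.0]


class TestTransientSelection:
    def test_gaussian_tail_fraction_matches_normal_sf(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 1, 100_000)
        frac = select_significant_transients(trace).mean()
        assert frac == pytest.approx(stats.norm.sf(3), rel=0.25)

    def test_constant_trace_empty_mask(self):
        assert not select_significant_transients(np.ones(50)).any()

    def test_single_large_spike_is_exactly_masked(self):
        trace = np.zeros(1000)
        trace[123] = 10.0
        mask = select_significant_transients(trace)
        assert mask.sum() == 1 and mask[123]


class TestTuning:
    def test_flat_events_give_flat_curve_smoothing_identity(self):
        amps = np.ones(6000)  # an event on every frame: rate uniform in space
        ev = uniform_train(amps)
        occ = compute_occupancy(ev.position_mm, ev.frame_period_s, L)
        curve = compute_tuning(ev, occ, track_length_mm=L)
        assert np.allclose(curve.rate, curve.rate[0], rtol=1e-9)

    def test_single_event_smoothing_wraps_symmetrically(self):
        amps = np.zeros(6000)
        amps[0] = 1.0  # event in bin 0
        ev = uniform_train(amps)
        occ = compute_occupancy(ev.position_mm, ev.frame_period_s, L)
        curve = compute_tuning(ev, occ, track_length_mm=L)
        assert curve.rate[1] == pytest.approx(curve.rate[B - 1], rel=1e-9)
        assert curve.rate[2] == pytest.approx(curve.rate[B - 2], rel=1e-9)

    def test_presmoothing_curve_conserves_event_count(self):
        rng = np.random.default_rng(1)
        amps = (rng.random(6000) < 0.02).astype(float)
        ev = uniform_train(amps)
        occ = compute_occupancy(ev.position_mm, ev.frame_period_s, L)
        curve = compute_tuning(ev, occ, track_length_mm=L)
        assert np.sum(curve.raw_rate * occ.dwell_s) == pytest.approx(
            amps.sum())

    def test_zero_occupancy_rejected(self):
        ev = uniform_train(np.zeros(10))
        occ = OccupancyMap(dwell_s=np.zeros(B), bin_width_mm=L / B)
        with pytest.raises(ValueError):
            compute_tuning(ev, occ, track_length_mm=L)


class TestShuffleThreshold:
    def test_same_seed_identical_thresholds(self):
        rng = np.random.default_rng(2)
        amps = (rng.random(6000) < 0.01).astype(float)
        ev = uniform_train(amps)
        occ = compute_occupancy(ev.position_mm, ev.frame_period_s, L)
        t1 = shuffle_threshold(ev, occ, n_shuffles=100, seed=9,
                               track_length_mm=L)
        t2 = shuffle_threshold(ev, occ, n_shuffles=100, seed=9,
                               track_length_mm=L)
        assert np.array_equal(t1, t2)

    def test_perfectly_tuned_cell_exceeds_threshold_at_its_bin(self):
        amps = np.zeros(12000)
        ev = uniform_train(amps, n_laps=8)
        target_bin = 20
        in_bin = (ev.position_mm // (L / B)).astype(int) == target_bin
        amps[in_bin] = 1.0
        ev = EventTrain(amps, 1 / 30.0, ev.position_mm, ev.lap)
        occ = compute_occupancy(ev.position_mm, ev.frame_period_s, L)
        curve = compute_tuning(ev, occ, track_length_mm=L)
        thr = shuffle_threshold(ev, occ, n_shuffles=200, seed=0,
                                track_length_mm=L)
        assert curve.rate[target_bin] > thr[target_bin]

    def test_needs_at_least_two_laps(self):
        ev = uniform_train(np.ones(100), n_laps=1)
        occ = compute_occupancy(ev.position_mm, ev.frame_period_s, L)
        with pytest.raises(ValueError):
            shuffle_threshold(ev, occ, n_shuffles=10, seed=0,
                              track_length_mm=L)


class TestFieldDetection:
    def curve_with_run(self, start, width):
        rate = np.zeros(B)
        idx = (start + np.arange(width)) % B
        rate[idx] = 2.0
        return TuningCurve(rate=rate, raw_rate=rate, counts=rate,
                           zero_dwell=np.zeros(B, bool))

    def laps_hitting(self, bins_hit, n_laps=10):
        return [np.array(bins_hit) for _ in range(n_laps)]

    def test_two_bins_insufficient(self):
        fields = detect_place_fields(self.curve_with_run(10, 2), np.ones(B),
                                     self.laps_hitting([10, 11]))
        assert fields == []

    def test_three_bins_accepted_12cm_minimum(self):
        fields = detect_place_fields(self.curve_with_run(10, 3), np.ones(B),
                                     self.laps_hitting([11]))
        assert len(fields) == 1 and fields[0].width_bins == 3

    def test_twentyfive_bins_rejected_100cm_cap(self):
        fields = detect_place_fields(self.curve_with_run(5, 25), np.ones(B),
                                     self.laps_hitting(list(range(5, 30))))
        assert fields == []

    def test_twentyfour_bins_still_admissible(self):
        fields = detect_place_fields(self.curve_with_run(5, 24), np.ones(B),
                                     self.laps_hitting([12]))
        assert len(fields) == 1 and fields[0].width_bins == 24

    def test_wrapping_run_detected_once(self):
        fields = detect_place_fields(self.curve_with_run(47, 6), np.ones(B),
                                     self.laps_hitting([48, 0]))
        assert len(fields) == 1
        assert fields[0].start_bin == 47 and fields[0].width_bins == 6

    def test_lap_reliability_rule_filters_sporadic_runs(self):
        curve = self.curve_with_run(10, 4)
        hits = [np.array([11]) if lap < 4 else np.array([], dtype=int)
                for lap in range(10)]  # events on 40% of laps only
        assert detect_place_fields(curve, np.ones(B), hits) == []


class TestFieldMetrics:
    def field(self, start, width):
        from looptrack.analysis import PlaceField
        return PlaceField(start_bin=start, end_bin=(start + width) % B,
                          n_bins_total=B, peak_bin=start)

    def test_sensitivity_every_lap(self):
        f = [self.field(10, 3)]
        laps = [np.array([11]) for _ in range(10)]
        assert sensitivity(f, laps) == 1.0

    def test_sensitivity_half_of_laps(self):
        f = [self.field(10, 3)]
        laps = [np.array([11]) if i < 5 else np.array([30])
                for i in range(10)]
        assert sensitivity(f, laps) == 0.5

    def test_sensitivity_tracks_bernoulli_rate(self):
        rng = np.random.default_rng(0)
        q = 0.7
        hit = rng.random(2000) < q
        laps = [np.array([11]) if h else np.array([], int) for h in hit]
        est = sensitivity([self.field(10, 3)], laps)
        assert est == pytest.approx(q, abs=3 * np.sqrt(q * (1 - q) / 2000))

    def test_specificity_all_in_field(self):
        laps = [np.array([10, 11, 12]) for _ in range(5)]
        assert specificity([self.field(10, 3)], laps) == 1.0

    def test_specificity_half_in_field_each_lap(self):
        laps = [np.array([11, 40]) for _ in range(5)]
        assert specificity([self.field(10, 3)], laps) == 0.5

    def test_specificity_hand_computed_mixture(self):
        laps = [np.array([11]),            # ratio 1
                np.array([11, 40]),        # ratio 0.5
                np.array([40]),            # ratio 0
                np.array([], dtype=int)]   # excluded
        assert specificity([self.field(10, 3)], laps) == pytest.approx(0.5)


class TestSpatialInformation:
    def occ_uniform(self):
        return OccupancyMap(dwell_s=np.ones(B), bin_width_mm=L / B)

    def curve(self, rate):
        return TuningCurve(rate=rate, raw_rate=rate, counts=rate,
                           zero_dwell=np.zeros(B, bool))

    def test_flat_curve_zero_bits(self):
        assert spatial_information(self.curve(np.full(B, 3.0)),
                                   self.occ_uniform()) == pytest.approx(0.0)

    def test_single_bin_uniform_occupancy_log2_B(self):
        rate = np.zeros(B)
        rate[7] = 5.0
        si = spatial_information(self.curve(rate), self.occ_uniform())
        assert si == pytest.approx(np.log2(B))

    def test_matches_independent_direct_sum(self):
        rng = np.random.default_rng(4)
        rate = rng.random(B) * 3
        dwell = rng.random(B) + 0.5
        occ = OccupancyMap(dwell_s=dwell, bin_width_mm=L / B)
        si = spatial_information(self.curve(rate), occ)
        # independent oracle: scalar loop over the defining sum
        p = dwell / dwell.sum()
        lam_bar = sum(p[i] * rate[i] for i in range(B))
        expected = sum(p[i] * (rate[i] / lam_bar) * np.log2(rate[i] / lam_bar)
                       for i in range(B) if rate[i] > 0)
        assert si == pytest.approx(expected, abs=1e-12)

    def test_non_negative_on_random_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            rate = rng.random(B)
            si = spatial_information(self.curve(rate), self.occ_uniform())
            assert si >= -1e-12


class TestRemapping:
    def test_identical_curves_correlate_to_one(self):
        rng = np.random.default_rng(6)
        c = rng.random(B)
        assert rate_map_correlation(c, c) == pytest.approx(1.0)

    def test_negated_curve_correlates_to_minus_one(self):
        rng = np.random.default_rng(7)
        c = rng.random(B)
        assert rate_map_correlation(c, 2 * c.mean() - c) == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(B), rng.random(B)
        r = rate_map_correlation(a, b)
        expected = (np.mean(a * b) - a.mean() * b.mean()) / (a.std() * b.std())
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(rate_map_correlation(np.ones(B), np.arange(B, dtype=float)))

    def test_exact_rotation_recovered(self):
        rng = np.random.default_rng(9)
        pop = rng.random((30, B))
        rolled = np.roll(pop, 7, axis=1)
        s, val = optimal_circular_shift(pop, rolled)
        assert s == 7 and val == pytest.approx(1.0)

    def test_self_shift_zero_with_unit_correlation(self):
        rng = np.random.default_rng(10)
        pop = rng.random((20, B))
        s, val = optimal_circular_shift(pop, pop)
        assert s == 0 and val == pytest.approx(1.0)

    def test_noisy_rotation_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        pop = rng.random((40, B))
        noisy = np.roll(pop, 13, axis=1) + rng.normal(0, 0.05, (40, B))
        s, _ = optimal_circular_shift(pop, noisy)
        # exhaustive oracle over all B candidate shifts
        def mean_corr(shift):
            rolled = np.roll(pop, shift, axis=1)
            return np.mean([np.corrcoef(rolled[:, b], noisy[:, b])[0, 1]
                            for b in range(B)])
        best = max(range(B), key=mean_corr)
        assert s == best == 13


class TestDecoder:
    def small_model(self, n_cells=3, n_bins=4, tau=0.5):
        m = BayesDecoder(n_bins=n_bins, tau_s=tau, frame_period_s=1 / 30.0)
        rng = np.random.default_rng(12)
        m.rates_ = rng.uniform(0.1, 3.0, (n_cells, n_bins))
        m.log_rates_ = np.log(m.rates_)
        m.n_cells_ = n_cells
        m.empty_bins_ = np.zeros(n_bins, bool)
        return m

    def test_zero_activity_uniform_rates_gives_uniform_posterior(self):
        m = self.small_model()
        m.rates_ = np.full((3, 4), 2.0)
        m.log_rates_ = np.log(m.rates_)
        post = decode_posterior(np.zeros(3), m)
        assert np.allclose(post, 0.25)

    def test_single_bin_cell_decodes_its_bin(self):
        m = BayesDecoder(n_bins=5, tau_s=0.5)
        X = np.zeros((50, 1))
        y = np.tile(np.arange(5), 10)
        X[y == 3, 0] = 1.0
        m.fit(X, y)
        assert m.predict(np.array([[4.0]]))[0] == 3

    def test_posterior_sums_to_one_and_matches_product_form(self):
        """Direct evaluation of C * prod f^a * exp(-tau sum f)."""
        m = self.small_model()
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = rng.integers(0, 5, size=3).astype(float)
            post = decode_posterior(a, m)
            assert post.sum() == pytest.approx(1.0, abs=1e-10)
            unnorm = np.array([
                np.prod(m.rates_[:, b] ** a) * np.exp(-m.tau_s *
                                                      m.rates_[:, b].sum())
                for b in range(4)])
            assert np.allclose(post, unnorm / unnorm.sum(), atol=1e-10)

    def test_argmax_tie_breaks_to_lowest_bin(self):
        m = BayesDecoder(n_bins=3, tau_s=0.5)
        m.rates_ = np.full((2, 3), 1.5)
        m.log_rates_ = np.log(m.rates_)
        m.n_cells_ = 2
        m.empty_bins_ = np.zeros(3, bool)
        assert m.predict(np.array([[1.0, 2.0]]))[0] == 0

    def test_fit_recovers_single_lap_average_on_identical_laps(self):
        rng = np.random.default_rng(14)
        one_lap_X = (rng.random((40, 6)) < 0.2).astype(float)
        one_lap_y = np.repeat(np.arange(4), 10)
        X = np.tile(one_lap_X, (5, 1))
        y = np.tile(one_lap_y, 5)
        m = fit_decoder(X, y, n_bins=4, frame_period_s=1.0, rate_floor=0.0)
        single = fit_decoder(one_lap_X, one_lap_y, n_bins=4,
                             frame_period_s=1.0, rate_floor=0.0)
        assert np.allclose(m.rates_, single.rates_)

    def test_rate_floor_keeps_posterior_finite(self):
        m = BayesDecoder(n_bins=3, tau_s=0.5, frame_period_s=1.0)
        X = np.zeros((30, 2))
        y = np.tile(np.arange(3), 10)
        X[y == 0, 0] = 1.0
        m.fit(X, y)
        post = decode_posterior(np.array([1.0, 1.0]), m)
        assert np.all(np.isfinite(post)) and post.sum() == pytest.approx(1.0)

    def test_sklearn_param_protocol(self):
        m = BayesDecoder(n_bins=10, tau_s=0.25)
        assert m.get_params()["tau_s"] == 0.25
        m.set_params(tau_s=1.0)
        assert m.tau_s == 1.0
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


class TestDecodingError:
    def test_perfect_decoding_zero_error(self):
        assert decoding_error(np.arange(10), np.arange(10), B) == 0.0

    def test_antipode_error_is_half_track(self):
        true = np.arange(10)
        decoded = (true + B // 2) % B
        assert decoding_error(decoded, true, B) == pytest.approx(100.0)

    def test_chance_level_closed_form(self):
        assert chance_level_circular(200.0) == 50.0
        assert chance_level_circular(400.0) == 100.0

    def test_chance_level_monte_carlo(self):
        rng = np.random.default_rng(15)
        n = 10**6
        a, b = rng.uniform(0, 200, n), rng.uniform(0, 200, n)
        d = np.abs(a - b)
        d = np.minimum(d, 200 - d)
        se = d.std() / np.sqrt(n)
        assert abs(d.mean() - 50.0) < 3 * se


class TestLabelShuffle:
    def test_tuned_population_beats_all_shuffles(self, suite_small):
        pop = suite_small["tuned_rich"]
        act = (pop.amplitudes > 0).astype(float)
        bins = ana.position_to_bin(pop.position_mm, L, B)
        train = pop.lap < pop.lap.max()
        m = fit_decoder(act[train], bins[train], B,
                        frame_period_s=pop.frame_period_s)
        wf = max(1, int(round(m.tau_s / m.frame_period_s)))
        A, truth = ana._window_counts(act[~train], bins[~train], wf)
        res = chance_by_label_shuffle(m, A, truth, n_shuffles=100, seed=1)
        assert res["observed_error_cm"] < res["shuffle_errors_cm"].min()
        assert res["p_value"] < 0.01


class TestTwoProportionZ:
    def test_equal_proportions_z_zero(self):
        z, p = two_proportion_ztest(30, 100, 60, 200)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_published_place_cell_counts(self):
        z, p = two_proportion_ztest(3253, 9195, 6101, 13454)
        assert round(z, 2) == 14.96
        assert p < 1e-49

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest
        rng = np.random.default_rng(16)
        for _ in range(25):
            n1, n2 = rng.integers(20, 500, 2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            z, p = two_proportion_ztest(k1, n1, k2, n2)
            z_ref, p_ref = proportions_ztest([k2, k1], [n2, n1])
            assert z == pytest.approx(z_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_degenerate_pool_flagged(self):
        with pytest.warns(UserWarning):
            z, p = two_proportion_ztest(0, 10, 0, 20)
        assert np.isnan(z)
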