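import numpy as np
import pytest
from scipy import stats as sps

import gazeclust as gc
from gazeclust.cluster import FrameStatSeries, PERMS3, _t_from_scores

from _oracles import brute_force_cluster_test


def make_series(eta, unit_kind="subject"):
    eta = np.asarray(eta, dtype=float)
    U, _, F = eta.shape
    return gc.LogRatioSeries(
        eta=eta,
        count_unmentioned=np.zeros_like(eta),
        count_critical=np.zeros_like(eta),
        unit_ids=np.arange(U),
        unit_kind=unit_kind,
        frame_starts_ms=np.arange(F) * 50.0,
        bin_width_ms=50.0,
    )


def series_from_scores(scores):
    """Series whose common-ground contrast scores equal ``scores``."""
    scores = np.asarray(scores, dtype=float)
    U, F = scores.shape
    eta = np.zeros((U, 3, F))
    eta[:, 1, :] = scores
    return make_series(eta)


def random_series(rng, n_units=8, n_frames=12):
    return make_series(rng.normal(size=(n_units, 3, n_frames)))


def make_stats(t, n_units=25):
    t = np.asarray(t, dtype=float)
    return FrameStatSeries(
        t=t,
        n_units=np.full(t.shape, n_units),
        frame_starts_ms=np.arange(t.size) * 50.0,
        bin_width_ms=50.0,
    )


class TestContrast:
    def test_paper_contrasts(self):
        assert gc.LINGUISTIC.weights == (-1.0, 0.5, 0.5)
        assert gc.COMMON_GROUND.weights == (0.0, 1.0, -1.0)

    @pytest.mark.parametrize("w", [(1.0, 1.0, 1.0), (0.0, 0.0, 0.0), (1.0, -1.0)])
    def test_invalid_weights_rejected(self, w):
        with pytest.raises(ValueError):
            gc.Contrast("bad", w)


class TestFrameStatistics:
    def test_hand_computed_t(self):
        """Scores (1.0, 1.2, 0.8, 1.0): t = 1.0 / (0.16330/2) = 12.2474."""
        series = series_from_scores(np.tile([[1.0], [1.2], [0.8], [1.0]], (1, 3)))
        stats = gc.frame_statistics(series, gc.COMMON_GROUND)
        np.testing.assert_allclose(stats.t, 12.247448714, rtol=1e-9)
        assert (stats.n_units == 4).all()
        assert (stats.df == 3).all()

    def test_negation_antisymmetry(self):
        rng = np.random.default_rng(2)
        series = random_series(rng)
        flipped = make_series(-series.eta)
        t1 = gc.frame_statistics(series, gc.LINGUISTIC).t
        t2 = gc.frame_statistics(flipped, gc.LINGUISTIC).t
        np.testing.assert_array_equal(t1, -t2)

    def test_zero_variance_untestable(self):
        series = series_from_scores(np.ones((5, 4)))
        stats = gc.frame_statistics(series, gc.COMMON_GROUND)
        assert np.isnan(stats.t).all()

    def test_missing_unit_dropped_per_frame(self):
        rng = np.random.default_rng(3)
        series = random_series(rng, n_units=6)
        series.eta[0, 2, 4] = np.nan  # unit 0 missing one condition at frame 4
        stats = gc.frame_statistics(series, gc.LINGUISTIC)
        assert stats.n_units[4] == 5
        assert (np.delete(stats.n_units, 4) == 6).all()


class TestDetectClusters:
    def test_hand_worked_run(self):
        """(0.1, 2.5, 2.6, 2.2, 0.3) at t_crit 2.07: one cluster, frames 1-3,
        mass 7.3."""
        clusters = gc.detect_clusters(make_stats([0.1, 2.5, 2.6, 2.2, 0.3]), t_crit=2.07)
        assert len(clusters) == 1
        c = clusters[0]
        assert (c.start_frame, c.end_frame, c.direction) == (1, 3, 1)
        assert c.mass == pytest.approx(7.3)
        assert (c.start_ms, c.end_ms) == (50.0, 200.0)

    def test_subthreshold_series_yields_nothing(self):
        assert gc.detect_clusters(make_stats([0.5, -1.0, 2.0]), t_crit=2.07) == []

    def test_sign_change_splits_runs(self):
        clusters = gc.detect_clusters(make_stats([2.5, -2.5]), t_crit=2.07)
        assert [(c.start_frame, c.end_frame) for c in clusters] == [(0, 0), (1, 1)]
        assert [c.mass for c in clusters] == [2.5, -2.5]
        assert [c.direction for c in clusters] == [1, -1]

    def test_default_critical_value_uses_t_distribution(self):
        stats = make_stats([2.5, 2.9], n_units=5)  # t_crit(0.975, df=4) = 2.776
        clusters = gc.detect_clusters(stats, alpha=0.05)
        assert [(c.start_frame, c.end_frame) for c in clusters] == [(1, 1)]

    def test_untestable_frames_break_runs(self):
        clusters = gc.detect_clusters(make_stats([2.5, np.nan, 2.5]), t_crit=2.07)
        assert [(c.start_frame, c.end_frame) for c in clusters] == [(0, 0), (2, 2)]


class TestMaxAbsMass:
    def test_matches_detect_clusters(self):
        rng = np.random.default_rng(4)
        t = rng.normal(scale=2.0, size=(40, 20))
        crit = np.full(20, 1.5)
        fast = gc.max_abs_cluster_masses(t, crit)
        for row, expect in zip(t, fast):
            clusters = gc.detect_clusters(make_stats(row), t_crit=1.5)
            slow = max((abs(c.mass) for c in clusters), default=0.0)
            assert expect == pytest.approx(slow)


class TestPermuteLabels:
    def test_identity_assignment_is_noop(self):
        rng = np.random.default_rng(0)
        series = random_series(rng)
        out = gc.permute_labels(series, rng, assignments=np.zeros(series.n_units, dtype=int))
        np.testing.assert_array_equal(out.eta, series.eta)

    def test_relabelling_conserves_values(self):
        rng = np.random.default_rng(1)
        series = random_series(rng)
        out = gc.permute_labels(series, rng)
        np.testing.assert_allclose(
            np.sort(out.eta, axis=1), np.sort(series.eta, axis=1)
        )

    def test_unbalanced_unit_rejected(self):
        rng = np.random.default_rng(1)
        series = random_series(rng)
        series.eta[2, 1, :] = np.nan
        with pytest.raises(ValueError, match="unbalanced"):
            gc.permute_labels(series, rng)

    def test_observed_rank_uniform_under_null(self, small_params):
        """Exchangeability: the observed per-frame |t| is an ordinary draw
        from its permutation distribution, so its normalized rank has mean
        ~1/2 across independent null datasets."""
        params = small_params.with_(n_subjects=9, curves=gc.null_curves())
        design = gc.generate_design(9, 6, 3)
        n_perm, frames = 39, [0, 1, 2, 3, 4]
        ranks = []
        for s in range(40):
            gaze = gc.generate_gaze(design, params, seed=1000 + s)
            series = gc.unit_log_ratio(gc.bin_samples(gaze, 500.0, (0.0, 2500.0)), "subject")
            t_obs = np.abs(gc.frame_statistics(series, gc.LINGUISTIC).t)
            rng = np.random.default_rng(s)
            t_perm = np.abs(
                [gc.frame_statistics(gc.permute_labels(series, rng), gc.LINGUISTIC).t
                 for _ in range(n_perm)]
            )
            ranks.append((t_perm[:, frames] < t_obs[frames]).mean(axis=0))
        mean_rank = np.mean(ranks, axis=0)
        assert (np.abs(mean_rank - 0.5) < 0.15).all()


class TestPermutationTest:
    def test_p_value_floor_and_ceiling(self):
        assert gc.cluster_p_value(5.0, np.zeros(999)) == pytest.approx(1 / 1000)
        assert gc.cluster_p_value(2.0, np.array([3.0])) == 1.0
        # ties count toward b (conservative)
        assert gc.cluster_p_value(2.0, np.array([2.0, 1.0, 3.0])) == 0.75

    def test_deterministic_and_pure(self):
        rng = np.random.default_rng(5)
        series = random_series(rng, n_units=10)
        series.eta[:, 1, 4:8] += 2.0  # plant an effect
        before = series.eta.copy()
        r1 = gc.permutation_test(series, gc.COMMON_GROUND, n_permutations=200, seed=3)
        r2 = gc.permutation_test(series, gc.COMMON_GROUND, n_permutations=200, seed=3)
        np.testing.assert_array_equal(series.eta, before)
        np.testing.assert_array_equal(r1.null_max_masses, r2.null_max_masses)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]
        assert r1.clusters and r1.min_p < 0.05

    def test_observed_statistics_match_frame_statistics(self):
        rng = np.random.default_rng(6)
        series = random_series(rng)
        report = gc.permutation_test(series, gc.LINGUISTIC, n_permutations=10, seed=0)
        np.testing.assert_array_equal(
            report.observed.t, gc.frame_statistics(series, gc.LINGUISTIC).t
        )

    def test_exhaustive_matches_brute_force_small(self):
        rng = np.random.default_rng(7)
        series = random_series(rng, n_units=4, n_frames=6)
        series.eta[:, 1, 2:5] += 2.5
        report = gc.permutation_test(series, gc.COMMON_GROUND, exhaustive=True)
        assert report.n_permutations == 6**4
        observed, ps, null = brute_force_cluster_test(
            series.eta, gc.COMMON_GROUND.weights, 0.05
        )
        assert len(report.clusters) == len(observed)
        for c, (s, e, m), p in zip(report.clusters, observed, ps):
            assert (c.start_frame, c.end_frame) == (s, e)
            assert c.mass == pytest.approx(m)
            assert c.p_value == p
        np.testing.assert_allclose(np.sort(report.null_max_masses), np.sort(null), atol=1e-9)

    def test_effect_size_monotonicity(self):
        """Raising the generative unmentioned-vs-critical separation never
        lowers the median observed maximum cluster mass."""
        design = gc.generate_design(12, 6, 3)
        medians = []
        for delta in (0.0, 0.08, 0.16):
            flat = gc.PreferenceCurve(
                (0.3, 0.3, 0.3, 0.1), (gc.Ramp((0.12, 0.39, 0.39, 0.10), 900.0, 150.0),)
            )
            ramp = gc.PreferenceCurve(
                (0.3, 0.3, 0.3, 0.1),
                (gc.Ramp((0.12, 0.39 + delta, 0.39 - delta, 0.10), 900.0, 150.0),),
            )
            params = gc.SyntheticParams(n_subjects=12, n_items=6,
                                        curves={"OS1P": flat, "OS2P": ramp, "TS2P": ramp})
            masses = []
            for s in range(50):
                gaze = gc.generate_gaze(design, params, seed=7000 + s)
                series = gc.unit_log_ratio(gc.bin_samples(gaze, 50.0, (0.0, 2500.0)), "subject")
                stats = gc.frame_statistics(series, gc.LINGUISTIC)
                crit = sps.t.ppf(0.975, 11)
                masses.append(gc.max_abs_cluster_masses(stats.t[None, :], np.full(50, crit))[0])
            medians.append(np.median(masses))
        assert medians[0] <= medians[1] <= medians[2]
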