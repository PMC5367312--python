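import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gazeclust as gc


def _constant_gaze(aoi: str, n_samp: int = 1250, subject=0, item=0, cond="OS1P"):
    t = np.arange(n_samp) * 2.0
    return pd.DataFrame(
        {"subject": subject, "item": item, "condition": cond, "t_ms": t, "aoi": aoi}
    )


class TestBinSamples:
    def test_frame_grid_arithmetic(self, small_binned, small_gaze):
        """2500 ms window at 500 Hz with 50 ms bins: 50 frames x 25 samples."""
        assert small_binned.n_frames == 50
        assert (small_binned.counts.sum(axis=2) == 25).all()
        assert small_binned.counts.sum() == len(small_gaze)

    def test_constant_gaze_counts(self):
        binned = gc.bin_samples(_constant_gaze("negated"), 50.0, (0.0, 2500.0))
        assert binned.counts.shape == (1, 50, 4)
        np.testing.assert_array_equal(binned.counts[0, :, 0], 25)
        np.testing.assert_array_equal(binned.counts[0, :, 1:], 0)

    def test_non_dividing_bin_width_rejected(self, small_gaze):
        with pytest.raises(ValueError, match="divide"):
            gc.bin_samples(small_gaze, 70.0, (0.0, 2500.0))

    def test_empty_dataset_rejected(self, small_gaze):
        with pytest.raises(ValueError, match="empty"):
            gc.bin_samples(small_gaze.iloc[:0], 50.0)

    def test_conflicting_condition_rejected(self):
        a = _constant_gaze("negated", cond="OS1P")
        b = _constant_gaze("critical", cond="OS2P")
        with pytest.raises(ValueError, match="more than one condition"):
            gc.bin_samples(pd.concat([a, b], ignore_index=True), 50.0, (0.0, 2500.0))

    def test_window_inference_matches_explicit(self, small_gaze):
        inferred = gc.bin_samples(small_gaze, 50.0)
        explicit = gc.bin_samples(small_gaze, 50.0, (0.0, 2500.0))
        np.testing.assert_array_equal(inferred.counts, explicit.counts)


class TestProportionSeries:
    def test_opposing_trials_split_evenly(self):
        a = _constant_gaze("negated", subject=0)
        b = _constant_gaze("critical", subject=1)
        binned = gc.bin_samples(pd.concat([a, b], ignore_index=True), 50.0, (0.0, 2500.0))
        prop = gc.proportion_series(binned)
        os1p = prop[prop["condition"] == "OS1P"]
        for label, expected in [("negated", 0.5), ("critical", 0.5), ("unmentioned", 0.0)]:
            assert (os1p.loc[os1p["aoi"] == label, "proportion"] == expected).all()

    def test_proportions_sum_to_one(self, small_binned):
        prop = gc.proportion_series(small_binned)
        sums = prop.groupby(["condition", "frame_index"], observed=True)["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


class TestLogRatio:
    def test_empirical_logit_value(self):
        assert gc.empirical_log_ratio(20, 10) == pytest.approx(math.log(20.5 / 10.5))
        assert gc.empirical_log_ratio(10, 10) == 0.0

    @given(cu=st.integers(0, 1000), cc=st.integers(0, 1000))
    def test_antisymmetry_and_finiteness(self, cu, cc):
        eta = gc.empirical_log_ratio(cu, cc)
        assert np.isfinite(eta)
        assert eta == pytest.approx(-gc.empirical_log_ratio(cc, cu))
        if cu == cc:
            assert eta == 0.0

    @given(cu=st.integers(0, 500), cc=st.integers(0, 500))
    def test_strict_monotonicity(self, cu, cc):
        assert gc.empirical_log_ratio(cu + 1, cc) > gc.empirical_log_ratio(cu, cc)
        assert gc.empirical_log_ratio(cu, cc + 1) < gc.empirical_log_ratio(cu, cc)

    def test_unit_pooling_is_ratio_of_sums(self, small_binned):
        series = gc.unit_log_ratio(small_binned, "subject")
        u0 = series.unit_ids[0]
        rows = small_binned.subject == u0
        cond0 = small_binned.condition[rows] == 0
        cu = small_binned.counts[rows][cond0, :, 1].sum(axis=0)
        cc = small_binned.counts[rows][cond0, :, 2].sum(axis=0)
        np.testing.assert_allclose(series.eta[0, 0], np.log((cu + 0.5) / (cc + 0.5)))
        np.testing.assert_array_equal(series.count_unmentioned[0, 0], cu)

    def test_missing_cell_flagged_not_fabricated(self, small_gaze):
        subj0 = small_gaze["subject"].iloc[0]
        mask = (small_gaze["subject"] == subj0) & (small_gaze["condition"] == "OS1P")
        binned = gc.bin_samples(small_gaze[~mask], 50.0, (0.0, 2500.0))
        series = gc.unit_log_ratio(binned, "subject")
        i = list(series.unit_ids).index(subj0)
        assert np.isnan(series.eta[i, 0]).all()
        assert np.isfinite(series.eta[i, 1:]).all()

    def test_large_count_convergence(self):
        """With a constant generating curve, the pooled log ratio converges to
        log(p_u/p_c) (here log(0.4/0.3)); per-unit whole-window etas agree
        within sampling error."""
        curve = gc.constant_curve((0.2, 0.4, 0.3, 0.1))
        params = gc.SyntheticParams(
            n_subjects=12, n_items=18, subject_sd_ms=0.0, item_sd_ms=0.0,
            curves={c: curve for c in gc.CONDITIONS},
        )
        gaze = gc.generate_gaze(gc.generate_design(12, 18, 3), params, seed=9)
        binned = gc.bin_samples(gaze, 2500.0, (0.0, 2500.0))
        series = gc.unit_log_ratio(binned, "subject")
        assert abs(np.nanmean(series.eta) - math.log(0.4 / 0.3)) < 0.15

    def test_unknown_unit_kind_rejected(self, small_binned):
        with pytest.raises(ValueError):
            gc.unit_log_ratio(small_binned, "trial")


def test_binned_and_series_export_shapes(small_binned):
    long = small_binned.to_frame()
    assert len(long) == small_binned.n_trials * small_binned.n_frames
    assert (long["n_samples"] == 25).all()
    series = gc.unit_log_ratio(small_binned, "item")
    tidy = series.to_frame()
    assert len(tidy) == series.n_units * 3 * series.n_frames
    assert set(tidy.columns) >= {"unit", "condition", "frame_index", "log_ratio"}
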