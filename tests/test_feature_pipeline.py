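"""Hourly binning, imputation, trend features and sample assembly."""

import numpy as np
import pytest

import troughcast as tc
from troughcast.feature_pipeline import (SEQ_HOURS, SKIP_FEATURES, HourlyGrid,
                                         NormalizationStats, bin_hourly,
                                         impute, trend_features)
from conftest import make_encounter


def obs(var, t, v):
    return tc.TimedObservation(var, t, v)


def stats_with_means(means):
    return NormalizationStats(means, np.zeros(1), np.ones(1),
                              np.zeros(len(SKIP_FEATURES)),
                              np.ones(len(SKIP_FEATURES)))


class TestBinHourly:
    def test_median_of_three(self):
        grid = bin_hourly([obs("x", 0.2, 10), obs("x", 0.5, 14),
                           obs("x", 0.9, 12)], 2, ("x",))
        assert grid.values[0, 0] == 12
        assert grid.mask[0, 0]

    def test_even_count_median(self):
        grid = bin_hourly([obs("x", 0.1, 10), obs("x", 0.6, 14)], 1, ("x",))
        assert grid.values[0, 0] == 12

    def test_missing_hour_masked(self):
        grid = bin_hourly([obs("x", 0.5, 1.0)], 5, ("x",))
        assert not grid.mask[3, 0]

    def test_negative_timestamp_rejected(self):
        with pytest.raises(ValueError):
            tc.TimedObservation("x", -1.0, 5.0)

    def test_one_value_per_hour_roundtrips(self):
        stream = [obs("x", h + 0.5, float(h)) for h in range(24)]
        grid = bin_hourly(stream, 24, ("x",))
        assert np.array_equal(grid.values[:, 0], np.arange(24.0))
        assert grid.mask.all()


class TestImpute:
    def test_locf_24h_boundary(self):
        observations = [obs("x", 5.5, 7.0)]
        grid = bin_hourly(observations, 40, ("x",))
        out = impute(grid, stats_with_means({"x": 99.0}))
        # hours 6..29 are within 24 h of the hour-5 value; hour 30 is not
        assert np.all(out.values[6:30, 0] == 7.0)
        assert np.all(out.values[30:, 0] == 99.0)

    def test_fully_observed_unchanged(self):
        stream = [obs("x", h + 0.5, float(h)) for h in range(10)]
        grid = bin_hourly(stream, 10, ("x",))
        out = impute(grid, stats_with_means({"x": 0.0}))
        assert np.array_equal(out.values, grid.values)

    def test_never_observed_gets_training_mean(self):
        grid = bin_hourly([], 6, ("x",))
        out = impute(grid, stats_with_means({"x": 3.5}))
        assert np.all(out.values[:, 0] == 3.5)

    def test_unknown_variable_error_names_it(self):
        grid = bin_hourly([obs("mystery", 0.5, 1.0)], 2, ("mystery",))
        with pytest.raises(KeyError, match="mystery"):
            impute(grid, stats_with_means({}))

    def test_idempotent(self):
        observations = [obs("x", 2.5, 4.0), obs("x", 30.5, 9.0)]
        grid = bin_hourly(observations, 60, ("x",))
        stats = stats_with_means({"x": 1.0})
        once = impute(grid, stats)
        twice = impute(once, stats)
        assert np.array_equal(once.values, twice.values)
        assert np.array_equal(once.mask, grid.mask)


class TestTrendFeatures:
    def test_linear_ramp_slope_one(self):
        values = np.arange(80, dtype=float)[:, None]
        grid = HourlyGrid(("x",), values, np.ones_like(values, dtype=bool))
        slope, mean = trend_features(grid, hour=80, window=72)["x"]
        assert slope == pytest.approx(1.0)

    def test_constant_series(self):
        values = np.full((80, 1), 5.5)
        grid = HourlyGrid(("x",), values, np.ones_like(values, dtype=bool))
        slope, mean = trend_features(grid, hour=80)["x"]
        assert slope == pytest.approx(0.0)
        assert mean == pytest.approx(5.5)

    def test_ramp_mean(self):
        values = np.arange(72, dtype=float)[:, None]
        grid = HourlyGrid(("x",), values, np.ones_like(values, dtype=bool))
        _, mean = trend_features(grid, hour=72, window=72)["x"]
        assert mean == pytest.approx(35.5)

    def test_short_history_uses_prefix(self):
        values = np.arange(10, dtype=float)[:, None]
        grid = HourlyGrid(("x",), values, np.ones_like(values, dtype=bool))
        slope, mean = trend_features(grid, hour=10, window=72)["x"]
        assert slope == pytest.approx(1.0)
        assert mean == pytest.approx(4.5)

    def test_single_point_slope_zero(self):
        values = np.array([[3.0]])
        grid = HourlyGrid(("x",), values, np.ones((1, 1), dtype=bool))
        slope, _ = trend_features(grid, hour=1)["x"]
        assert slope == 0.0


class TestAssembledSamples:
    def test_shapes_and_completeness(self, fitted_pipeline, small_samples):
        train_samples, test_samples = small_samples
        F = fitted_pipeline.schema.n_seq
        for s in train_samples + test_samples:
            assert s.sequence.shape == (SEQ_HOURS, F)
            assert np.isfinite(s.sequence).all()
            assert s.skip_features.shape == (len(SKIP_FEATURES),)

    def test_skip_dose_windows(self, fitted_pipeline):
        """Interval dose counts only doses strictly after prediction time."""
        enc = make_encounter(
            stay_hours=240.0,
            doses=[(32.0, 1000.0), (60.0, 750.0), (84.0, 750.0)],
            troughs=[(95.0, 12.0)],
            observations=[("scr", float(h), 1.0) for h in range(0, 120, 12)],
        )
        (inst,) = tc.select_eligible([enc])
        pipe = tc.FeaturePipeline()
        (sample,) = pipe.fit_transform([inst])
        skip = dict(zip(SKIP_FEATURES, sample.skip_features))
        assert skip["day_dose_mg"] == 1000.0  # dose at 32 h, day 1
        assert skip["interval_dose_mg"] == 1500.0  # 60 h and 84 h doses
        assert skip["hours_since_last_dose"] == pytest.approx(16.0)
        assert skip["prior_trough_present"] == 0.0

    def test_prior_trough_mean_fill(self, fitted_pipeline, small_samples):
        train_samples, _ = small_samples
        fill = fitted_pipeline.stats.variable_means["_prior_trough"]
        missing = [s for s in train_samples
                   if s.skip_features[SKIP_FEATURES.index("prior_trough_present")] == 0]
        for s in missing:
            assert s.skip_features[SKIP_FEATURES.index("prior_trough_mg_per_L")] \
                == pytest.approx(fill)

    def test_train_only_statistics(self, small_split):
        """Fitting on train alone equals fitting while test exists (no leakage)."""
        train, test = small_split
        stats_a = tc.FeaturePipeline().fit(train).stats
        stats_b = tc.FeaturePipeline().fit(train).stats  # test never passed in
        assert np.array_equal(stats_a.seq_mean, stats_b.seq_mean)
        # and a pipeline fit on a different split has different stats
        other_train, _ = tc.split_train_test(train + test, 0.6, seed=99)
        stats_c = tc.FeaturePipeline().fit(other_train).stats
        assert not np.array_equal(stats_a.seq_mean, stats_c.seq_mean)

    def test_z_scoring_centres_continuous_features(self, fitted_pipeline,
                                                   small_samples):
        train_samples, _ = small_samples
        schema = fitted_pipeline.schema
        stacked = np.concatenate([s.sequence for s in train_samples], axis=0)
        cont = [j for j, n in enumerate(schema.sequence_features)
                if n not in schema.categorical]
        means = stacked[:, cont].mean(axis=0)
        assert np.all(np.abs(means) < 1e-6)

    def test_categorical_features_stay_binary(self, fitted_pipeline,
                                              small_samples):
        train_samples, _ = small_samples
        schema = fitted_pipeline.schema
        cat = [j for j, n in enumerate(schema.sequence_features)
               if n in schema.categorical]
        stacked = np.concatenate([s.sequence for s in train_samples], axis=0)
        assert set(np.unique(stacked[:, cat])) <= {0.0, 1.0}
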