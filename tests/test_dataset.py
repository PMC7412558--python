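"""Windowing, split schemes, data-quality filters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glucast import (
    ChannelSeries, EventSchedule, SplitSpec,
    apply_sample_mask, build_windows, fill_gaps,
    filter_forecast_event_windows, filter_unrecorded_meal_segments,
    split_samples,
)


def _series(bg, dt=15.0, carbs=None):
    n = len(bg)
    z = np.zeros(n)
    return ChannelSeries(np.datetime64("2024-01-01"), dt, np.asarray(bg, float),
                         z if carbs is None else np.asarray(carbs, float),
                         z.copy(), z.copy())


def test_window_shape_and_target(one_day_series):
    samples = build_windows(one_day_series, 540.0)
    assert len(samples) == len(one_day_series) - 36
    s = samples[10]
    assert s.stacked().shape == (36, 4)
    assert s.target_delta == pytest.approx(
        one_day_series.bg[s.end_index + 1] - one_day_series.bg[s.end_index])


def test_exact_length_series_yields_no_samples():
    assert build_windows(_series(np.arange(36.0)), 540.0) == []


@settings(deadline=None, derandomize=True)
@given(length=st.integers(min_value=37, max_value=400))
def test_window_count_formula(length):
    """One window per valid end position: count = L - W."""
    samples = build_windows(_series(np.linspace(80, 200, length)), 540.0)
    assert len(samples) == length - 36


def test_constant_series_has_zero_deltas():
    samples = build_windows(_series(np.full(80, 120.0)), 540.0)
    assert all(s.target_delta == 0.0 for s in samples)


@settings(deadline=None, derandomize=True)
@given(n=st.integers(min_value=40, max_value=300),
       frac=st.floats(min_value=0.1, max_value=0.9),
       seed=st.integers(min_value=0, max_value=99))
def test_random_split_is_partition(n, frac, seed):
    samples = build_windows(_series(np.linspace(70, 180, n)), 540.0)
    spec = SplitSpec(mode="random_fraction", train_fraction=frac, seed=seed)
    train, val = split_samples(samples, spec)
    assert len(train) + len(val) == len(samples)
    ids = {id(s) for s in samples}
    assert {id(s) for s in train} | {id(s) for s in val} == ids
    assert not ({id(s) for s in train} & {id(s) for s in val})
    assert len(train) == round(frac * len(samples))


def test_random_split_seventy_thirty():
    samples = build_windows(_series(np.linspace(70, 180, 1036)), 540.0)
    train, val = split_samples(samples, SplitSpec(train_fraction=0.7, seed=1))
    assert (len(train), len(val)) == (700, 300)


def test_day_split_validation_from_final_days():
    """10-day record, 8 training days: all val windows end in days 9-10."""
    n = 10 * 96
    samples = build_windows(_series(np.linspace(70, 180, n)), 540.0)
    train, val = split_samples(samples, SplitSpec(mode="by_day", train_days=8),
                               dt_min=15.0)
    cutoff = 8 * 96
    assert all(s.end_index < cutoff for s in train)
    assert all(s.end_index >= cutoff for s in val)
    assert len(train) + len(val) == len(samples)


def test_split_spec_validation():
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=1.0)
    with pytest.raises(ValueError):
        SplitSpec(mode="by_day", train_days=0)
    with pytest.raises(ValueError):
        split_samples([], SplitSpec())


class TestUnrecordedMealFilter:
    def test_quiet_series_fully_retained(self):
        mask = filter_unrecorded_meal_segments(_series(np.full(100, 110.0)))
        assert not mask.any()

    def test_unexplained_rise_flagged_and_windows_dropped(self):
        bg = np.full(100, 100.0)
        bg[50:55] += np.linspace(0, 80, 5)  # +80 mg/dL over 60 min, no meal
        bg[55:] = 180.0
        series = _series(bg)
        mask = filter_unrecorded_meal_segments(series, 50.0, 60.0)
        assert mask[50:55].any()
        samples = build_windows(series, 540.0)
        kept = apply_sample_mask(samples, mask, 36)
        flagged_idx = set(np.flatnonzero(mask).tolist())
        for s in kept:
            assert not flagged_idx & set(range(s.end_index - 35, s.end_index + 2))
        assert len(kept) < len(samples)

    def test_rise_with_recorded_meal_retained(self):
        bg = np.full(100, 100.0)
        bg[50:55] += np.linspace(0, 80, 5)
        bg[55:] = 180.0
        carbs = np.zeros(100)
        carbs[48] = 60.0  # meal 30 min before onset
        mask = filter_unrecorded_meal_segments(_series(bg, carbs=carbs), 50.0, 60.0)
        assert not mask.any()

    def test_idempotent(self):
        bg = np.full(100, 100.0)
        bg[50:55] += np.linspace(0, 80, 5)
        series = _series(bg)
        m1 = filter_unrecorded_meal_segments(series, 50.0, 60.0)
        samples = build_windows(series, 540.0)
        once = apply_sample_mask(samples, m1, 36)
        twice = apply_sample_mask(once, m1, 36)
        assert twice == once


class TestForecastEventFilter:
    def _samples(self, n=120):
        return build_windows(_series(np.linspace(80, 160, n)), 540.0)

    def test_no_events_all_retained(self):
        events = EventSchedule((), (), (), duration_min=120 * 15.0)
        samples = self._samples()
        assert filter_forecast_event_windows(samples, events, 30.0, 15.0) == samples

    def test_event_inside_horizon_excluded(self):
        samples = self._samples()
        s = samples[5]
        t_meal = s.end_index * 15.0 + 10.0  # 10 min after window end
        events = EventSchedule(((t_meal, 40.0),), (), (), duration_min=120 * 15.0)
        kept = filter_forecast_event_windows(samples, events, 30.0, 15.0)
        assert s not in kept

    def test_event_beyond_horizon_retained(self):
        samples = self._samples()
        s = samples[5]
        t_meal = s.end_index * 15.0 + 90.0
        events = EventSchedule(((t_meal, 40.0),), (), (), duration_min=120 * 15.0)
        kept = filter_forecast_event_windows(samples, events, 30.0, 15.0)
        assert s in kept

    def test_idempotent(self):
        samples = self._samples()
        events = EventSchedule(((samples[5].end_index * 15.0 + 10.0, 40.0),),
                               (), (), duration_min=120 * 15.0)
        once = filter_forecast_event_windows(samples, events, 30.0, 15.0)
        twice = filter_forecast_event_windows(once, events, 30.0, 15.0)
        assert twice == once


def test_fill_gaps_locf_and_segmentation():
    bg = np.linspace(100, 150, 50)
    bg[10:12] = np.nan          # short gap: filled
    bg[30:40] = np.nan          # long gap: split
    series = _series(bg)
    parts = fill_gaps(series, max_gap_samples=2)
    assert len(parts) == 2
    assert parts[0].bg[10] == parts[0].bg[9] == parts[0].bg[11]
    assert not any(np.isnan(p.bg).any() for p in parts)
    assert len(parts[0]) + len(parts[1]) == 50 - 10
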