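"""Windowing, split schemes and data-quality filters.

Turns a :class:`~glucast.simulator.ChannelSeries` into supervised samples:
a sliding window of W = window_span_min / dt_min samples over all four
channels, labelled with the next-sample BG variation (delta-BG). Provides
the two validation protocols (seeded random 70-30 split over windows, and
a leading-days/trailing-days split) and the two real-data filters: dropping
segments with large unexplained BG rises (unrecorded meals) and dropping
validation windows with meal/insulin events inside the forecast horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import ChannelSeries, EventSchedule

__all__ = [
    "WindowSample",
    "SplitSpec",
    "Normalizer",
    "build_windows",
    "split_samples",
    "filter_unrecorded_meal_segments",
    "apply_sample_mask",
    "filter_forecast_event_windows",
    "fill_gaps",
]


@dataclass(frozen=True, eq=False)
class WindowSample:
    """One supervised sample: a W-long 4-channel window plus its target.

    ``target_delta`` is bg[end_index + 1] - bg[end_index] in mg/dL;
    ``end_index`` locates the last window sample in the source series.
    """

    bg_window: np.ndarray
    carb_window: np.ndarray
    fast_window: np.ndarray
    slow_window: np.ndarray
    target_delta: float
    end_index: int

    def stacked(self) -> np.ndarray:
        """(W, 4) array in channel order bg, carbs, fast, slow."""
        return np.column_stack(
            [self.bg_window, self.carb_window, self.fast_window, self.slow_window]
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation split protocol.

    mode "random_fraction": seeded shuffle of windows, first
    ``train_fraction`` to train. mode "by_day": windows ending within the
    first ``train_days`` days go to train, the rest to validation.
    """

    mode: str = "random_fraction"
    train_fraction: float = 0.7
    train_days: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("random_fraction", "by_day"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "random_fraction" and not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be strictly between 0 and 1")
        if self.mode == "by_day" and self.train_days < 1:
            raise ValueError("train_days must be >= 1")


def window_length(window_span_min: float, dt_min: float) -> int:
    w = int(round(window_span_min / dt_min))
    if w < 1:
        raise ValueError("window span shorter than one sample")
    return w


def build_windows(series: ChannelSeries, window_span_min: float = 540.0) -> list[WindowSample]:
    """Contiguous stride-1 windows with next-sample delta targets.

    Returns one sample per position where both a full window and its
    successor BG reading exist: len(series) - W samples (empty if the
    series is too short).
    """
    w = window_length(window_span_min, series.dt_min)
    n = len(series)
    samples: list[WindowSample] = []
    for end in range(w - 1, n - 1):
        lo = end - w + 1
        samples.append(
            WindowSample(
                bg_window=series.bg[lo : end + 1],
                carb_window=series.carbs[lo : end + 1],
                fast_window=series.insulin_fast[lo : end + 1],
                slow_window=series.insulin_slow[lo : end + 1],
                target_delta=float(series.bg[end + 1] - series.bg[end]),
                end_index=end,
            )
        )
    return samples


def split_samples(
    samples: list[WindowSample], spec: SplitSpec, dt_min: float = 15.0
) -> tuple[list[WindowSample], list[WindowSample]]:
    """Partition samples into (train, validation) per the split spec."""
    if not samples:
        raise ValueError("cannot split an empty sample list")
    if spec.mode == "random_fraction":
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(len(samples))
        n_train = int(round(spec.train_fraction * len(samples)))
        train_idx = set(order[:n_train].tolist())
        train = [s for i, s in enumerate(samples) if i in train_idx]
        val = [s for i, s in enumerate(samples) if i not in train_idx]
        return train, val
    # by_day: first train_days * (1440 / dt) sample indices belong to training
    cutoff = spec.train_days * int(round(1440.0 / dt_min))
    train = [s for s in samples if s.end_index < cutoff]
    val = [s for s in samples if s.end_index >= cutoff]
    return train, val


def filter_unrecorded_meal_segments(
    series: ChannelSeries,
    rise_threshold: float = 50.0,
    rise_window_min: float = 60.0,
    meal_lookback_min: float = 60.0,
) -> np.ndarray:
    """Flag samples inside large BG rises not explained by a recorded meal.

    Scans all index pairs (i, j) with t_j - t_i <= rise_window_min; when
    bg[j] - bg[i] >= rise_threshold and no meal is recorded in
    (t_i - meal_lookback_min, t_j], samples i..j are flagged. Returns a
    boolean mask (True = flagged/excluded) over the series samples; combine
    with :func:`apply_sample_mask` to drop overlapping windows.
    """
    if rise_threshold <= 0 or rise_window_min <= 0:
        raise ValueError("thresholds must be positive")
    n = len(series)
    dt = series.dt_min
    span = int(rise_window_min // dt)
    lookback = int(meal_lookback_min // dt)
    meal_at = series.carbs > 0
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, min(i + span, n - 1) + 1):
            if series.bg[j] - series.bg[i] >= rise_threshold:
                lo = max(0, i - lookback)
                if not meal_at[lo : j + 1].any():
                    flagged[i : j + 1] = True
    return flagged


def apply_sample_mask(samples: list[WindowSample], flagged: np.ndarray,
                      window_len: int) -> list[WindowSample]:
    """Drop windows overlapping any flagged source sample (target included)."""
    kept = []
    for s in samples:
        lo = s.end_index - window_len + 1
        if not flagged[lo : s.end_index + 2].any():
            kept.append(s)
    return kept


def filter_forecast_event_windows(
    samples: list[WindowSample],
    events: EventSchedule,
    horizon_min: float,
    dt_min: float,
) -> list[WindowSample]:
    """Drop windows with any meal/bolus event strictly inside the horizon.

    An event at time t (minutes from series start) excludes a window ending
    at sample e when t lies in (e*dt, e*dt + horizon_min]. With events in
    the forecast span zeroed by contract, such windows cannot be predicted
    from the information given to the model.
    """
    if horizon_min <= 0:
        raise ValueError("horizon_min must be positive")
    times = np.array([t for t, amount in events.all_events if amount > 0])
    if times.size == 0:
        return list(samples)
    kept = []
    for s in samples:
        t_end = s.end_index * dt_min
        if not np.any((times > t_end) & (times <= t_end + horizon_min)):
            kept.append(s)
    return kept


def fill_gaps(series: ChannelSeries, max_gap_samples: int = 2) -> list[ChannelSeries]:
    """Handle missing CGM readings (NaN in bg).

    Gaps of at most ``max_gap_samples`` are filled by carrying the last
    observation forward; longer gaps break the record into independent
    segments, returned in order. Event channels are preserved as-is.
    """
    bg = series.bg
    isnan = np.isnan(bg)
    if not isnan.any():
        return [series]
    # locate runs of NaN
    segments: list[tuple[int, int]] = []  # [start, end) of kept stretches
    breaks = [0]
    i = 0
    n = len(bg)
    filled = bg.copy()
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            run = j - i
            if run <= max_gap_samples and i > 0:
                filled[i:j] = filled[i - 1]
            else:
                segments.append((breaks[-1], i))
                breaks.append(j)
            i = j
        else:
            i += 1
    segments.append((breaks[-1], n))
    out = []
    step = np.timedelta64(int(round(series.dt_min * 60)), "s")
    for lo, hi in segments:
        if hi - lo == 0:
            continue
        out.append(
            ChannelSeries(
                start_time=series.start_time + step * lo,
                dt_min=series.dt_min,
                bg=filled[lo:hi],
                carbs=series.carbs[lo:hi],
                insulin_fast=series.insulin_fast[lo:hi],
                insulin_slow=series.insulin_slow[lo:hi],
            )
        )
    return out


class Normalizer:
    """Per-channel z-score standardization fit on training windows only.

    Targets stay in mg/dL; only model inputs are standardized. Channels
    with zero variance (e.g. an all-zero bolus channel) use scale 1.
    """

    def __init__(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.mean = np.asarray(mean, dtype=float)  # (4,)
        self.std = np.asarray(std, dtype=float)

    @classmethod
    def fit(cls, samples: list[WindowSample]) -> "Normalizer":
        if not samples:
            raise ValueError("cannot fit a normalizer on no samples")
        x = np.stack([s.stacked() for s in samples])  # (n, W, 4)
        mean = x.mean(axis=(0, 1))
        std = x.std(axis=(0, 1))
        std = np.where(std < 1e-8, 1.0, std)
        return cls(mean, std)

    def transform(self, windows: np.ndarray) -> np.ndarray:
        """windows: (..., 4) in physical units -> standardized."""
        return (windows - self.mean) / self.std

    def transform_bg(self, bg: np.ndarray | float) -> np.ndarray | float:
        return (bg - self.mean[0]) / self.std[0]

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(np.array(d["mean"]), np.array(d["std"]))
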