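"""Recursive multi-step blood-glucose forecasting.

The trained model predicts one-step BG variations only; longer horizons are
reached by unrolling: predict the delta, form the next BG level, slide the
window forward one sample with the predicted BG and zeros in the meal and
insulin channels (future exogenous inputs are unknown at forecast time and
are zeroed by contract), and repeat. The forecast therefore answers "what
happens if the patient takes no further action".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import WindowSample
from .model import TrainedModel

__all__ = ["ForecastTrace", "horizon_to_steps", "recursive_forecast", "forecast_batch"]

BG_FLOOR = 20.0
BG_SATURATION = 400.0


@dataclass
class ForecastTrace:
    """A predicted BG trajectory from one window origin."""

    horizon_min: float
    steps: int
    predicted_bg: np.ndarray
    reference_bg: np.ndarray | None = None
    origin_index: int = -1


def horizon_to_steps(horizon_min: float, dt_min: float) -> int:
    """Number of recursive one-sample steps covering the horizon exactly."""
    steps = horizon_min / dt_min
    if abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"horizon {horizon_min} min is not a multiple of dt {dt_min} min "
            f"(remainder {horizon_min % dt_min:g} min)"
        )
    return int(round(steps))


def forecast_batch(model: TrainedModel, windows: np.ndarray, steps: int,
                   bg_floor: float = BG_FLOOR,
                   bg_saturation: float = BG_SATURATION) -> np.ndarray:
    """Vectorized recursive forecast for a batch of windows.

    windows: (B, W, 4) in physical units. Returns predicted BG levels of
    shape (B, steps). Each appended sample carries the predicted BG
    (clamped to the sensor range) and zeroed exogenous channels.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    windows = np.array(windows, dtype=float, copy=True)
    B = windows.shape[0]
    out = np.empty((B, steps))
    for s in range(steps):
        delta = np.asarray(model.predict_delta(windows))
        next_bg = np.clip(windows[:, -1, 0] + delta, bg_floor, bg_saturation)
        out[:, s] = next_bg
        windows[:, :-1, :] = windows[:, 1:, :]
        windows[:, -1, :] = 0.0
        windows[:, -1, 0] = next_bg
    return out


def recursive_forecast(model: TrainedModel, window, steps: int,
                       reference_bg: np.ndarray | None = None,
                       bg_floor: float = BG_FLOOR,
                       bg_saturation: float = BG_SATURATION) -> ForecastTrace:
    """Unroll the one-step model ``steps`` times from a single window."""
    origin = -1
    if isinstance(window, WindowSample):
        origin = window.end_index
        window = window.stacked()
    window = np.asarray(window, dtype=float)
    pred = forecast_batch(model, window[None], steps, bg_floor, bg_saturation)[0]
    ref = None if reference_bg is None else np.asarray(reference_bg, dtype=float)
    return ForecastTrace(
        horizon_min=steps * model.config.dt_min,
        steps=steps,
        predicted_bg=pred,
        reference_bg=ref,
        origin_index=origin,
    )
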