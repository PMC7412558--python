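"""Forecast scoring: RMSE, Clarke Error Grid, sweeps and transfer tests.

RMSE follows the conventional sqrt(mean((Gm - Ge)^2)) over measured and
estimated BG pairs. Clinical accuracy uses the Clarke Error Grid, which
zones each (reference, predicted) pair A-E: A is clinically accurate
(within 20% of reference, or both hypoglycemic), B benign, C would trigger
overcorrection, D misses an out-of-range event, E suggests treatment
opposite to what is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SplitSpec, WindowSample, build_windows, split_samples
from .forecast import forecast_batch, horizon_to_steps
from .model import NetConfig, TrainedModel, build_model, train
from .simulator import ChannelSeries

__all__ = [
    "RmseReport", "ClarkeReport", "SweepReport",
    "rmse", "clarke_zone", "clarke_counts",
    "fit_patient", "horizon_forecast_pairs", "evaluate_horizon",
    "run_sweep", "transfer_evaluate",
]

ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class RmseReport:
    horizon_min: float
    n_points: int
    rmse: float


@dataclass(frozen=True)
class ClarkeReport:
    counts: dict[str, int]
    zones: tuple[str, ...] = ()

    @property
    def n_points(self) -> int:
        return sum(self.counts.values())

    def fraction(self, zone: str) -> float:
        return self.counts.get(zone, 0) / self.n_points


@dataclass
class SweepReport:
    """RMSE (mg/dL) per memory-unit count and prediction horizon."""

    units: tuple[int, ...]
    horizons: tuple[float, ...]
    cells: dict[tuple[int, float], float] = field(default_factory=dict)

    def table(self) -> str:
        head = "Memory units" + "".join(f"\t{int(h)} min" for h in self.horizons)
        rows = [head]
        for u in self.units:
            rows.append(str(u) + "".join(f"\t{self.cells[(u, h)]:.2f}"
                                         for h in self.horizons))
        return "\n".join(rows)


def rmse(measured, estimated, horizon_min: float = 0.0) -> RmseReport:
    """Root-mean-square error between measured and estimated BG (mg/dL)."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    if m.size == 0:
        raise ValueError("need at least one point")
    return RmseReport(horizon_min=horizon_min, n_points=m.size,
                      rmse=float(np.sqrt(np.mean((m - e) ** 2))))


def clarke_zone(reference: float, predicted: float) -> str:
    """Clarke Error Grid zone for one (reference, predicted) BG pair.

    Standard piecewise boundaries; zone A covers predictions within 20% of
    the reference or pairs that are both in the hypoglycemic range.
    """
    r, p = float(reference), float(predicted)
    if r <= 0 or p <= 0:
        raise ValueError("BG values must be positive")
    if (r <= 70 and p <= 70) or abs(p - r) <= 0.2 * r:
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= (7.0 / 5.0) * r - 182):
        return "C"
    if (r >= 240 and 70 <= p <= 180) or (r <= 175.0 / 3.0 and 70 <= p <= 180) \
            or (175.0 / 3.0 <= r <= 70 and p >= (6.0 / 5.0) * r):
        return "D"
    return "B"


def clarke_counts(pairs) -> ClarkeReport:
    """Zone counts over (reference, predicted) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one pair")
    zones = tuple(clarke_zone(r, p) for r, p in pairs)
    counts = {z: 0 for z in ZONES}
    for z in zones:
        counts[z] += 1
    return ClarkeReport(counts=counts, zones=zones)


# Pipeline helpers -----------------------------------------------------------


def fit_patient(series: ChannelSeries, config: NetConfig,
                split: SplitSpec) -> tuple[TrainedModel, list[WindowSample]]:
    """Window one patient's record, split, train; return model + val set."""
    samples = build_windows(series, config.window_span_min)
    train_set, val_set = split_samples(samples, split, dt_min=series.dt_min)
    model = build_model(config)
    train(model, train_set, config)
    return model, val_set


def horizon_forecast_pairs(
    model: TrainedModel,
    val_samples: list[WindowSample],
    series: ChannelSeries,
    horizon_min: float,
    *,
    all_steps: bool = False,
    exclude_saturated: bool = True,
    saturation: float = 400.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(reference, predicted) BG pairs for recursive forecasts at a horizon.

    By default scores only the final step of each trace (the prediction at
    exactly the horizon); ``all_steps`` scores every intermediate step too.
    Reference samples pinned at the sensor saturation ceiling are treated
    as measurement errors and excluded by default.
    """
    steps = horizon_to_steps(horizon_min, series.dt_min)
    usable = [s for s in val_samples if s.end_index + steps < len(series)]
    if not usable:
        return np.array([]), np.array([])
    windows = np.stack([s.stacked() for s in usable])
    predicted = forecast_batch(model, windows, steps)
    reference = np.stack(
        [series.bg[s.end_index + 1 : s.end_index + steps + 1] for s in usable]
    )
    if all_steps:
        ref, pred = reference.ravel(), predicted.ravel()
    else:
        ref, pred = reference[:, -1], predicted[:, -1]
    if exclude_saturated:
        keep = ref < saturation
        ref, pred = ref[keep], pred[keep]
    return ref, pred


def evaluate_horizon(model, val_samples, series, horizon_min,
                     **kwargs) -> tuple[RmseReport, ClarkeReport]:
    """RMSE and Clarke report for recursive forecasts at one horizon."""
    ref, pred = horizon_forecast_pairs(model, val_samples, series,
                                       horizon_min, **kwargs)
    report = rmse(ref, pred, horizon_min=horizon_min)
    clarke = clarke_counts(zip(ref, pred))
    return report, clarke


def run_sweep(
    cohort,
    units_list,
    horizons,
    split: SplitSpec,
    seed: int = 0,
    base_config: NetConfig | None = None,
) -> SweepReport:
    """Train one model per memory-unit value per patient; tabulate RMSE.

    ``cohort`` is a list of (params, schedule, series) from the simulator
    (or any iterable whose last element is a ChannelSeries). Cell values
    average the per-patient final-step RMSE at each horizon.
    """
    units_list = tuple(int(u) for u in units_list)
    horizons = tuple(float(h) for h in horizons)
    if not units_list:
        raise ValueError("units_list must be non-empty")
    series_list = [entry[-1] for entry in cohort]
    if not series_list:
        raise ValueError("cohort is empty")
    base = base_config or NetConfig(dt_min=series_list[0].dt_min, seed=seed)
    report = SweepReport(units=units_list, horizons=horizons)
    for u in units_list:
        cfg = NetConfig(**{**_cfg_dict(base), "memory_units": u, "seed": seed})
        per_h = {h: [] for h in horizons}
        for series in series_list:
            model, val = fit_patient(series, cfg, split)
            for h in horizons:
                r, _ = evaluate_horizon(model, val, series, h)
                per_h[h].append(r.rmse)
        for h in horizons:
            report.cells[(u, h)] = float(np.mean(per_h[h]))
    return report


def _cfg_dict(cfg: NetConfig) -> dict:
    from dataclasses import asdict
    return asdict(cfg)


def transfer_evaluate(model: TrainedModel, series: ChannelSeries,
                      horizon_min: float, split: SplitSpec) -> RmseReport:
    """Score a model trained on one patient against another patient's data.

    The donor model's weights and normalization statistics are applied
    unchanged to the recipient's validation windows; a large gap versus
    within-patient error indicates the learned dynamics are person-specific.
    """
    samples = build_windows(series, model.config.window_span_min)
    _, val = split_samples(samples, split, dt_min=series.dt_min)
    ref, pred = horizon_forecast_pairs(model, val, series, horizon_min)
    return rmse(ref, pred, horizon_min=horizon_min)
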