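"""Synthetic type-1-diabetes cohort simulator.

Generates multi-day, uniformly sampled four-channel patient records
(blood glucose from a CGM, carbohydrate intake, fast- and slow-acting
insulin boluses) from a minimal kinetic model: gamma-shaped absorption
kernels for meals and boluses feeding a first-order glucose balance with
endogenous return-to-basal and renal clearance above threshold.

The simulator is a stand-in for full physiological models (it is tuned to
qualitative realism, not to any published parameter set): meals raise BG,
insulin lowers it, glucose is cleared renally above ~180 mg/dL, and the
sensor clamps at a floor and a 400 mg/dL saturation ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "PatientParams",
    "EventSchedule",
    "ChannelSeries",
    "carb_absorption_profile",
    "insulin_action_profile",
    "simulate_patient",
    "generate_cohort",
    "sample_patient_params",
    "random_daily_schedule",
]


@dataclass(frozen=True)
class PatientParams:
    """Per-patient metabolic constants.

    Units: sensitivities in (mg/dL) per g and (mg/dL) per U of total
    absorbed action; rate constants in 1/min; time constants in min;
    glucose levels in mg/dL.
    """

    basal_bg: float = 110.0
    carb_sensitivity: float = 3.0
    insulin_sensitivity: float = 40.0
    glucose_decay: float = 0.02
    carb_tau: float = 45.0
    fast_tau: float = 55.0
    slow_tau: float = 300.0
    renal_threshold: float = 180.0
    renal_rate: float = 0.01
    bg_floor: float = 20.0
    bg_saturation: float = 400.0

    def __post_init__(self) -> None:
        for name in ("carb_tau", "fast_tau", "slow_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.fast_tau >= self.slow_tau:
            raise ValueError("fast_tau must be < slow_tau")
        if not (self.bg_floor < self.basal_bg < self.renal_threshold < self.bg_saturation):
            raise ValueError(
                "require bg_floor < basal_bg < renal_threshold < bg_saturation"
            )


@dataclass(frozen=True)
class EventSchedule:
    """Timed meal and bolus events over a simulation span.

    Each event is (time_min, amount); meals in grams, boluses in units.
    """

    meals: tuple[tuple[float, float], ...]
    fast_boluses: tuple[tuple[float, float], ...]
    slow_boluses: tuple[tuple[float, float], ...]
    duration_min: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "meals", tuple(map(tuple, self.meals)))
        object.__setattr__(self, "fast_boluses", tuple(map(tuple, self.fast_boluses)))
        object.__setattr__(self, "slow_boluses", tuple(map(tuple, self.slow_boluses)))
        for kind in ("meals", "fast_boluses", "slow_boluses"):
            for t, amount in getattr(self, kind):
                if not (0 <= t < self.duration_min):
                    raise ValueError(
                        f"{kind} event at t={t} outside [0, {self.duration_min})"
                    )
                if amount < 0:
                    raise ValueError(f"{kind} amount must be >= 0, got {amount}")

    @property
    def all_events(self) -> tuple[tuple[float, float], ...]:
        return self.meals + self.fast_boluses + self.slow_boluses


@dataclass
class ChannelSeries:
    """Aligned uniformly sampled four-channel record for one patient.

    ``bg`` is mg/dL; ``carbs``/``insulin_fast``/``insulin_slow`` carry each
    event's full amount in the sample bin containing its time (impulse
    encoding), zero elsewhere.
    """

    start_time: np.datetime64
    dt_min: float
    bg: np.ndarray
    carbs: np.ndarray
    insulin_fast: np.ndarray
    insulin_slow: np.ndarray

    def __post_init__(self) -> None:
        self.bg = np.asarray(self.bg, dtype=float)
        self.carbs = np.asarray(self.carbs, dtype=float)
        self.insulin_fast = np.asarray(self.insulin_fast, dtype=float)
        self.insulin_slow = np.asarray(self.insulin_slow, dtype=float)
        n = len(self.bg)
        if not (len(self.carbs) == len(self.insulin_fast) == len(self.insulin_slow) == n):
            raise ValueError("all four channel arrays must have equal length")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")

    def __len__(self) -> int:
        return len(self.bg)

    @property
    def timestamps(self) -> np.ndarray:
        step = np.timedelta64(int(round(self.dt_min * 60)), "s")
        return self.start_time + step * np.arange(len(self))

    def channels(self) -> np.ndarray:
        """Stack as (n_samples, 4) in order bg, carbs, fast, slow."""
        return np.column_stack([self.bg, self.carbs, self.insulin_fast, self.insulin_slow])


def _gamma_rate(amount: float, tau: float, t_grid: np.ndarray) -> np.ndarray:
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    if amount < 0:
        raise ValueError(f"amount must be >= 0, got {amount}")
    t = np.asarray(t_grid, dtype=float)
    tp = np.maximum(t, 0.0)
    with np.errstate(under="ignore"):
        rate = np.where(t >= 0, amount * (tp / tau**2) * np.exp(-tp / tau), 0.0)
    return rate


def carb_absorption_profile(dose: float, tau: float, t_grid: np.ndarray) -> np.ndarray:
    """Rate of carbohydrate appearance (g/min) after a meal of ``dose`` grams.

    Gamma kernel ``dose * t/tau^2 * exp(-t/tau)``: zero at ingestion, peak
    at ``t = tau``, unit total mass, so the full dose is eventually absorbed.
    """
    return _gamma_rate(dose, tau, t_grid)


def insulin_action_profile(units: float, tau: float, t_grid: np.ndarray) -> np.ndarray:
    """Insulin action rate (U-equivalents/min) after a bolus of ``units``.

    Same gamma kernel as carbohydrate absorption; fast- and slow-acting
    preparations differ only in their time constant ``tau``.
    """
    return _gamma_rate(units, tau, t_grid)


def _total_rate(events: Sequence[tuple[float, float]], tau: float,
                t_grid: np.ndarray) -> np.ndarray:
    """Superpose per-event gamma kernels on the grid."""
    total = np.zeros_like(t_grid, dtype=float)
    for t0, amount in events:
        if amount > 0:
            total += _gamma_rate(amount, tau, t_grid - t0)
    return total


def _bin_events(events: Sequence[tuple[float, float]], n: int, dt_min: float) -> np.ndarray:
    out = np.zeros(n)
    for t0, amount in events:
        idx = int(t0 // dt_min)
        if not 0 <= idx < n:
            raise ValueError(f"event at t={t0} falls outside the sampled span")
        out[idx] += amount
    return out


def simulate_patient(
    params: PatientParams,
    schedule: EventSchedule,
    dt_min: float = 15.0,
    seed: int | None = None,
    *,
    noise_std: float = 0.0,
    g0: float | None = None,
    internal_dt: float = 1.0,
    start_time: np.datetime64 | str = "2024-01-01T00:00:00",
) -> ChannelSeries:
    """Integrate the glucose balance over the schedule and sample a CGM trace.

    dG/dt = Scarb*Ra(t) - Sins*Ia(t) - kd*(G - Gb) - kr*max(0, G - Gr),
    with Ra/Ia the superposed meal/bolus kernels, explicit Euler at
    ``internal_dt`` minutes (default 1), clamped to the sensor range and
    subsampled to ``dt_min``. Optional i.i.d. Gaussian CGM noise is added
    after integration (then re-clamped).
    """
    n_samples = int(round(schedule.duration_min / dt_min))
    if abs(n_samples * dt_min - schedule.duration_min) > 1e-9:
        raise ValueError("schedule duration must be a multiple of dt_min")

    n_fine = int(round(schedule.duration_min / internal_dt))
    t_fine = np.arange(n_fine + 1) * internal_dt
    ra = _total_rate(schedule.meals, params.carb_tau, t_fine)
    ia = (_total_rate(schedule.fast_boluses, params.fast_tau, t_fine)
          + _total_rate(schedule.slow_boluses, params.slow_tau, t_fine))

    g = np.empty(n_fine + 1)
    g[0] = params.basal_bg if g0 is None else float(g0)
    for k in range(n_fine):
        dgdt = (params.carb_sensitivity * ra[k]
                - params.insulin_sensitivity * ia[k]
                - params.glucose_decay * (g[k] - params.basal_bg)
                - params.renal_rate * max(0.0, g[k] - params.renal_threshold))
        g[k + 1] = g[k] + internal_dt * dgdt
        g[k + 1] = min(max(g[k + 1], params.bg_floor), params.bg_saturation)

    stride = int(round(dt_min / internal_dt))
    bg = g[::stride][:n_samples].copy()
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        bg = bg + rng.normal(0.0, noise_std, size=bg.shape)
        bg = np.clip(bg, params.bg_floor, params.bg_saturation)

    return ChannelSeries(
        start_time=np.datetime64(start_time),
        dt_min=dt_min,
        bg=bg,
        carbs=_bin_events(schedule.meals, n_samples, dt_min),
        insulin_fast=_bin_events(schedule.fast_boluses, n_samples, dt_min),
        insulin_slow=_bin_events(schedule.slow_boluses, n_samples, dt_min),
    )


# Cohort generation ---------------------------------------------------------

#: Uniform sampling ranges for per-patient constants; levels in mg/dL,
#: taus in min, decay in 1/min. Calibrated once to give realistic
#: excursions (occasional <70 and >180 mg/dL) under the default schedule.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "basal_bg": (90.0, 140.0),
    "carb_sensitivity": (2.0, 4.0),
    "insulin_sensitivity": (30.0, 50.0),
    "glucose_decay": (0.015, 0.03),
    "carb_tau": (30.0, 60.0),
    "fast_tau": (40.0, 70.0),
    "slow_tau": (240.0, 360.0),
}

#: Daily schedule policy: three meals with a fast bolus each, one evening
#: slow (basal) bolus; times jittered uniformly within +/-60 min.
MEAL_HOURS = (7.0, 13.0, 19.0)
MEAL_GRAMS = (30.0, 90.0)
FAST_UNITS = (2.0, 8.0)
SLOW_UNITS = (10.0, 20.0)
SLOW_HOUR = 22.0
TIME_JITTER_MIN = 60.0


def sample_patient_params(rng: np.random.Generator) -> PatientParams:
    """Draw one patient's constants from the documented uniform ranges."""
    drawn = {k: rng.uniform(lo, hi) for k, (lo, hi) in PARAM_RANGES.items()}
    return PatientParams(**drawn)


def random_daily_schedule(rng: np.random.Generator, n_days: int) -> EventSchedule:
    """Randomize meals/boluses independently for every day.

    Times, hours and amounts differ between days, so held-out days carry
    genuinely unseen input patterns.
    """
    meals, fast, slow = [], [], []
    for day in range(n_days):
        base = day * 1440.0
        for hour in MEAL_HOURS:
            t = base + hour * 60.0 + rng.uniform(-TIME_JITTER_MIN, TIME_JITTER_MIN)
            meals.append((t, rng.uniform(*MEAL_GRAMS)))
            fast.append((t, rng.uniform(*FAST_UNITS)))
        t_slow = base + SLOW_HOUR * 60.0 + rng.uniform(-TIME_JITTER_MIN, TIME_JITTER_MIN)
        slow.append((t_slow, rng.uniform(*SLOW_UNITS)))
    return EventSchedule(tuple(meals), tuple(fast), tuple(slow),
                         duration_min=n_days * 1440.0)


def generate_cohort(
    n_patients: int,
    n_days: int,
    dt_min: float = 15.0,
    seed: int = 0,
    *,
    noise_std: float = 0.0,
) -> list[tuple[PatientParams, EventSchedule, ChannelSeries]]:
    """Simulate a cohort; fully reproducible from ``seed``."""
    if n_patients < 1 or n_days < 1:
        raise ValueError("n_patients and n_days must be >= 1")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_patients):
        params = sample_patient_params(rng)
        schedule = random_daily_schedule(rng, n_days)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        series = simulate_patient(params, schedule, dt_min, seed=noise_seed,
                                  noise_std=noise_std)
        cohort.append((params, schedule, series))
    return cohort
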