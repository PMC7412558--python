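"""Physiology-structured recurrent delta-BG model.

Four independent LSTM encoders — one per input signal (blood glucose,
carbohydrates, fast-acting insulin, slow-acting insulin) — each read out at
their final hidden state. The three exogenous encoder outputs are combined
by a dense rectified layer (stage 1, mirroring how carbohydrate digestion
and the two insulin absorption processes jointly set the glucose flux);
stage 2 combines that output with the BG encoder state, and a linear head
emits the predicted next-sample BG variation in mg/dL.

Training minimizes mean squared error on delta-BG with Adam, with early
stopping on a held-out tenth of the training windows. All randomness is
driven by the config seed; single-threaded runs are bit-reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml

from .dataset import Normalizer, WindowSample
from .nn import Adam, init_dense, init_lstm, lstm_backward, lstm_forward

__all__ = ["NetConfig", "TrainedModel", "DivergenceError",
           "build_model", "train", "predict_delta"]

_ENCODERS = ("bg", "carb", "fast", "slow")  # channel order in stacked windows
_EXOGENOUS = ("carb", "fast", "slow")


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training hyperparameters."""

    memory_units: int = 10
    window_span_min: float = 540.0
    dt_min: float = 15.0
    combiner_width: int = 8
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    early_stop_patience: int = 20
    holdout_fraction: float = 0.1
    loss: str = "mse"

    def __post_init__(self) -> None:
        if self.memory_units < 1:
            raise ValueError("memory_units must be >= 1")
        w = self.window_span_min / self.dt_min
        if abs(w - round(w)) > 1e-9 or round(w) < 1:
            raise ValueError("window_span_min must be a positive multiple of dt_min")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error training is supported")

    @property
    def window_len(self) -> int:
        return int(round(self.window_span_min / self.dt_min))


def _init_params(config: NetConfig) -> dict[str, np.ndarray]:
    rng = np.random.default_rng(config.seed)
    h, c = config.memory_units, config.combiner_width
    params: dict[str, np.ndarray] = {}
    for name in _ENCODERS:
        for k, v in init_lstm(rng, h).items():
            params[f"{name}.{k}"] = v
    for k, v in init_dense(rng, 3 * h, c).items():
        params[f"comb1.{k}"] = v
    for k, v in init_dense(rng, c + h, c).items():
        params[f"comb2.{k}"] = v
    for k, v in init_dense(rng, c, 1).items():
        params[f"head.{k}"] = v
    return params


def _forward(params: dict, x: np.ndarray, config: NetConfig,
             want_cache: bool = False):
    """x: (B, W, 4) standardized. Returns predictions (B,) [and cache]."""
    h = config.memory_units
    enc_out, enc_cache = {}, {}
    for idx, name in enumerate(_ENCODERS):
        sub = {k: params[f"{name}.{k}"] for k in ("Wx", "Wh", "b")}
        enc_out[name], enc_cache[name] = lstm_forward(sub, x[:, :, idx])
    z1_in = np.concatenate([enc_out[n] for n in _EXOGENOUS], axis=1)
    a1 = z1_in @ params["comb1.W"] + params["comb1.b"]
    z1 = np.maximum(a1, 0.0)
    z2_in = np.concatenate([z1, enc_out["bg"]], axis=1)
    a2 = z2_in @ params["comb2.W"] + params["comb2.b"]
    z2 = np.maximum(a2, 0.0)
    y = (z2 @ params["head.W"] + params["head.b"])[:, 0]
    if not want_cache:
        return y
    cache = {"enc_cache": enc_cache, "z1_in": z1_in, "a1": a1, "z1": z1,
             "z2_in": z2_in, "a2": a2, "z2": z2, "h": h}
    return y, cache


def _backward(params: dict, cache: dict, dy: np.ndarray,
              config: NetConfig) -> dict[str, np.ndarray]:
    h = config.memory_units
    grads: dict[str, np.ndarray] = {}
    dy2 = dy[:, None]
    grads["head.W"] = cache["z2"].T @ dy2
    grads["head.b"] = dy2.sum(axis=0)
    dz2 = dy2 @ params["head.W"].T
    da2 = dz2 * (cache["a2"] > 0)
    grads["comb2.W"] = cache["z2_in"].T @ da2
    grads["comb2.b"] = da2.sum(axis=0)
    dz2_in = da2 @ params["comb2.W"].T
    dz1 = dz2_in[:, : config.combiner_width]
    de_bg = dz2_in[:, config.combiner_width :]
    da1 = dz1 * (cache["a1"] > 0)
    grads["comb1.W"] = cache["z1_in"].T @ da1
    grads["comb1.b"] = da1.sum(axis=0)
    dz1_in = da1 @ params["comb1.W"].T
    de = {"bg": de_bg}
    for i, name in enumerate(_EXOGENOUS):
        de[name] = dz1_in[:, i * h : (i + 1) * h]
    for name in _ENCODERS:
        sub = {k: params[f"{name}.{k}"] for k in ("Wx", "Wh", "b")}
        g = lstm_backward(sub, cache["enc_cache"][name], de[name])
        for k, v in g.items():
            grads[f"{name}.{k}"] = v
    return grads


@dataclass
class TrainedModel:
    """Weights + config + training-set normalization, ready to predict."""

    params: dict[str, np.ndarray]
    config: NetConfig
    normalizer: Normalizer | None = None
    loss_history: list[float] = field(default_factory=list)

    def predict_delta(self, windows: np.ndarray | WindowSample) -> np.ndarray | float:
        """Predicted next-sample BG change (mg/dL) for physical-unit input.

        Accepts a single :class:`WindowSample`, one (W, 4) window or a
        batch (B, W, 4); returns a scalar for single-window input.
        """
        single = False
        if isinstance(windows, WindowSample):
            windows = windows.stacked()
        windows = np.asarray(windows, dtype=float)
        if windows.ndim == 2:
            windows = windows[None]
            single = True
        w = self.config.window_len
        if windows.shape[1:] != (w, 4):
            raise ValueError(f"expected windows of shape (B, {w}, 4), got {windows.shape}")
        x = self.normalizer.transform(windows) if self.normalizer else windows
        y = _forward(self.params, x, self.config)
        return float(y[0]) if single else y

    def summary(self) -> str:
        n_params = sum(v.size for v in self.params.values())
        lines = [f"PhysioLSTM: 4 recurrent encoders ({self.config.memory_units} "
                 f"memory units each), 2 combiner stages "
                 f"(width {self.config.combiner_width}), linear head",
                 f"window: {self.config.window_len} samples x 4 channels "
                 f"({self.config.window_span_min:g} min at {self.config.dt_min:g} min)",
                 f"parameters: {n_params}"]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.params)
        meta = {"config": asdict(self.config),
                "normalizer": self.normalizer.to_dict() if self.normalizer else None,
                "loss_history": [float(v) for v in self.loss_history]}
        (path / "config.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = yaml.safe_load((path / "config.yaml").read_text())
        with np.load(path / "weights.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        norm = Normalizer.from_dict(meta["normalizer"]) if meta["normalizer"] else None
        return cls(params=params, config=NetConfig(**meta["config"]),
                   normalizer=norm, loss_history=meta.get("loss_history", []))


def build_model(config: NetConfig) -> TrainedModel:
    """Seeded weight initialization; the model is untrained until `train`."""
    return TrainedModel(params=_init_params(config), config=config)


def _as_arrays(samples: list[WindowSample]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.stacked() for s in samples])
    y = np.array([s.target_delta for s in samples])
    return x, y


def train(model: TrainedModel, train_samples: list[WindowSample],
          config: NetConfig | None = None) -> TrainedModel:
    """Fit the model in place on windowed samples; returns the model.

    A tenth of the samples (seeded draw) is held out of gradient updates
    and monitored for early stopping (patience ``early_stop_patience``);
    the best weights seen are restored. Per-epoch training MSE lands in
    ``model.loss_history``.
    """
    if not train_samples:
        raise ValueError("empty training set")
    config = config or model.config
    rng = np.random.default_rng(config.seed + 1)
    x_all, y_all = _as_arrays(train_samples)

    model.normalizer = Normalizer.fit(train_samples)
    x_all = model.normalizer.transform(x_all)

    n = len(train_samples)
    n_hold = int(round(config.holdout_fraction * n)) if n >= 20 else 0
    order = rng.permutation(n)
    hold_idx, fit_idx = order[:n_hold], order[n_hold:]
    x_fit, y_fit = x_all[fit_idx], y_all[fit_idx]
    x_hold, y_hold = x_all[hold_idx], y_all[hold_idx]

    params = model.params
    opt = Adam(params, lr=config.learning_rate)
    best_monitor = np.inf
    best_params = None
    since_best = 0
    model.loss_history = []

    for epoch in range(config.epochs):
        perm = rng.permutation(len(x_fit))
        epoch_sse = 0.0
        for lo in range(0, len(perm), config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            xb, yb = x_fit[idx], y_fit[idx]
            pred, cache = _forward(params, xb, config, want_cache=True)
            err = pred - yb
            epoch_sse += float(err @ err)
            dy = 2.0 * err / len(err)
            grads = _backward(params, cache, dy, config)
            opt.step(params, grads)
        epoch_loss = epoch_sse / len(x_fit)
        model.loss_history.append(epoch_loss)
        if not np.isfinite(epoch_loss):
            raise DivergenceError(f"training loss diverged at epoch {epoch}")

        if n_hold:
            res = _forward(params, x_hold, config) - y_hold
            monitor = float(res @ res) / n_hold
        else:
            monitor = epoch_loss
        if monitor < best_monitor - 1e-12:
            best_monitor = monitor
            best_params = copy.deepcopy(params)
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.early_stop_patience:
                break

    if best_params is not None:
        model.params = best_params
    return model


def predict_delta(model: TrainedModel, windows) -> np.ndarray | float:
    """Functional alias for :meth:`TrainedModel.predict_delta`."""
    return model.predict_delta(windows)
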