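"""Network architecture, gradient correctness, training behavior."""

import copy

import numpy as np
import pytest

from glucast import NetConfig, WindowSample, build_model, train
from glucast.dataset import Normalizer
from glucast.model import _backward, _forward, _init_params

TINY = NetConfig(memory_units=3, combiner_width=4, window_span_min=75.0,
                 dt_min=15.0, seed=0)  # W = 5


def _random_samples(n, w=5, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        bg = rng.uniform(80, 200, w)
        # learnable target: a linear functional of the window plus noise
        target = 0.05 * (bg[-1] - bg[0]) + rng.normal(0, 0.5)
        out.append(WindowSample(
            bg_window=bg,
            carb_window=rng.uniform(0, 5, w),
            fast_window=rng.uniform(0, 1, w),
            slow_window=rng.uniform(0, 1, w),
            target_delta=float(target),
            end_index=w - 1 + k,
        ))
    return out


def test_gradients_match_finite_differences():
    """Analytic BPTT gradient of the MSE loss vs. central differences."""
    rng = np.random.default_rng(1)
    params = _init_params(TINY)
    x = rng.normal(size=(3, 5, 4))
    y = rng.normal(size=3)

    pred, cache = _forward(params, x, TINY, want_cache=True)
    dy = 2.0 * (pred - y) / len(y)
    grads = _backward(params, cache, dy, TINY)

    def loss(p):
        out = _forward(p, x, TINY)
        return float(np.mean((out - y) ** 2))

    eps = 1e-6
    rng2 = np.random.default_rng(2)
    for name, g in grads.items():
        flat_idx = rng2.choice(params[name].size, size=min(6, params[name].size),
                               replace=False)
        for idx in flat_idx:
            p = {k: v.copy() for k, v in params.items()}
            p[name].flat[idx] += eps
            up = loss(p)
            p[name].flat[idx] -= 2 * eps
            down = loss(p)
            numeric = (up - down) / (2 * eps)
            assert g.flat[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


def test_architecture_shape_and_param_growth():
    model = build_model(TINY)
    summary = model.summary()
    assert "4 recurrent encoders" in summary and "2 combiner stages" in summary
    n3 = sum(v.size for v in model.params.values())
    n10 = sum(v.size for v in build_model(
        NetConfig(memory_units=10, combiner_width=4, window_span_min=75.0,
                  dt_min=15.0)).params.values())
    assert n10 > n3
    # one weight set per encoder, two combiners, one head
    encoders = {k.split(".")[0] for k in model.params if k.split(".")[0]
                not in ("comb1", "comb2", "head")}
    assert encoders == {"bg", "carb", "fast", "slow"}


@pytest.mark.parametrize("units", [5, 10, 15])
def test_memory_unit_sweep_values_build(units):
    cfg = NetConfig(memory_units=units, window_span_min=75.0, dt_min=15.0)
    model = build_model(cfg)
    model.normalizer = Normalizer(np.zeros(4), np.ones(4))
    out = model.predict_delta(np.zeros((5, 4)))
    assert np.isfinite(out)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        NetConfig(memory_units=0)
    with pytest.raises(ValueError):
        NetConfig(window_span_min=100.0, dt_min=15.0)  # non-integral W


def test_training_reduces_loss_and_is_deterministic():
    samples = _random_samples(200, seed=5)
    cfg = NetConfig(**{**TINY.__dict__, "epochs": 15, "seed": 9})
    m1 = train(build_model(cfg), samples, cfg)
    m2 = train(build_model(cfg), samples, cfg)
    assert m1.loss_history[-1] < m1.loss_history[0]
    assert m1.loss_history == m2.loss_history
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])


def test_overfits_tiny_corpus():
    """With 10 samples and many epochs the net should memorize them."""
    samples = _random_samples(10, seed=2)
    cfg = NetConfig(memory_units=8, combiner_width=8, window_span_min=75.0,
                    dt_min=15.0, epochs=500, batch_size=10,
                    learning_rate=3e-3, seed=0, early_stop_patience=500)
    model = train(build_model(cfg), samples, cfg)
    pred = model.predict_delta(np.stack([s.stacked() for s in samples]))
    y = np.array([s.target_delta for s in samples])
    assert float(np.sqrt(np.mean((pred - y) ** 2))) < 1.0


def test_constant_corpus_predicts_near_zero_delta():
    w = 5
    samples = [WindowSample(np.full(w, 120.0), np.zeros(w), np.zeros(w),
                            np.zeros(w), 0.0, w - 1 + i) for i in range(30)]
    cfg = NetConfig(**{**TINY.__dict__, "epochs": 50})
    model = train(build_model(cfg), samples, cfg)
    assert abs(model.predict_delta(samples[0])) < 1.0


def test_empty_training_set_rejected():
    with pytest.raises(ValueError):
        train(build_model(TINY), [], TINY)


def test_batch_composition_invariance(tiny_trained):
    """Same window alone or inside a batch gives the same prediction."""
    model, val, _ = tiny_trained
    batch = np.stack([s.stacked() for s in val[:8]])
    together = model.predict_delta(batch)
    alone = [model.predict_delta(s) for s in val[:8]]
    assert np.allclose(together, alone, atol=1e-12)


def test_shape_mismatch_rejected(tiny_trained):
    model, _, _ = tiny_trained
    with pytest.raises(ValueError):
        model.predict_delta(np.zeros((4, 4)))


def test_save_load_roundtrip(tiny_trained, tmp_path):
    model, val, _ = tiny_trained
    model.save(tmp_path / "artifact")
    loaded = type(model).load(tmp_path / "artifact")
    assert loaded.config == model.config
    x = val[0]
    assert loaded.predict_delta(x) == pytest.approx(model.predict_delta(x), abs=1e-12)
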