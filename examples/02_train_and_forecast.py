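"""Train a personalized model and score recursive 30/60-min forecasts.

One patient's 10-day record is split 70-30 over its 9-h windows; the model
learns next-sample BG variations and is unrolled (with future meal/insulin
inputs zeroed) to each horizon. RMSE is in mg/dL: lower is better, and the
60-min figure is expected to exceed the 30-min one.
"""

from glucast import NetConfig, SplitSpec, generate_cohort
from glucast.evaluation import evaluate_horizon, fit_patient

params, schedule, series = generate_cohort(1, 10, 15.0, seed=1)[0]
cfg = NetConfig(memory_units=10, dt_min=15.0, seed=1)
split = SplitSpec(mode="random_fraction", train_fraction=0.7, seed=1)

model, val = fit_patient(series, cfg, split)
print(model.summary())
for horizon in (30.0, 60.0):
    report, clarke = evaluate_horizon(model, val, series, horizon)
    print(f"horizon {int(horizon):2d} min: RMSE {report.rmse:5.2f} mg/dL "
          f"over {report.n_points} forecasts, "
          f"Zone A {100 * clarke.fraction('A'):.1f}%")
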