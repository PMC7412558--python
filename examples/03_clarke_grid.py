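"""Clarke Error Grid zoning of forecasts.

Zones grade clinical consequences: A = accurate (within 20% of reference,
or both values hypoglycemic), B = benign error, C = would trigger an
overcorrection, D = misses a hypo/hyperglycemic event, E = suggests
treatment opposite to what is needed.
"""

from glucast import NetConfig, SplitSpec, clarke_counts, generate_cohort
from glucast.evaluation import fit_patient, horizon_forecast_pairs

params, schedule, series = generate_cohort(1, 10, 15.0, seed=2)[0]
cfg = NetConfig(memory_units=10, dt_min=15.0, epochs=60, seed=2)
split = SplitSpec(train_fraction=0.7, seed=2)
model, val = fit_patient(series, cfg, split)

ref, pred = horizon_forecast_pairs(model, val, series, horizon_min=30.0)
report = clarke_counts(zip(ref, pred))
print(f"{report.n_points} (reference, predicted) pairs at 30 min:")
for zone in "ABCDE":
    print(f"  Zone {zone}: {report.counts[zone]:4d} "
          f"({100 * report.fraction(zone):5.1f}%)")
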