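"""Sweep the per-encoder memory-unit count over {5, 10, 15}.

Reproduces the hyperparameter protocol: one model per unit count per
patient, scored by final-step RMSE at 30- and 60-min horizons. Too few
units underfit the absorption dynamics; too many overfit the windows.
(A two-patient cohort keeps this example to a few minutes.)
"""

from glucast import NetConfig, SplitSpec, generate_cohort, run_sweep

cohort = generate_cohort(2, 10, 15.0, seed=1)
split = SplitSpec(train_fraction=0.7, seed=1)
base = NetConfig(dt_min=15.0, seed=1)
report = run_sweep(cohort, units_list=(5, 10, 15), horizons=(30.0, 60.0),
                   split=split, seed=1, base_config=base)
print(report.table())
print("(cells are mean RMSE in mg/dL across patients; rows = memory units)")
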