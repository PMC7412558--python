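# Methods

## Problem

People with type 1 diabetes dose insulin against meals using intermittent
information from a continuous glucose monitor (CGM). Short-horizon forecasts
of blood glucose (BG) — 30 and 60 minutes ahead — give time to pre-empt
hypo- and hyperglycemic episodes. `glucast` builds such forecasts from four
uniformly sampled signals per patient: CGM glucose (mg/dL), carbohydrate
intake (g), and fast- and slow-acting insulin boluses (U).

## Model

The forecaster mirrors the structure of compartmental glucose–insulin
models rather than treating the four channels as one multivariate series.
Each signal gets its own LSTM encoder of `memory_units` hidden units
(default 10), read out at its final hidden state, so each encoder can learn
the memory of one physiological process: carbohydrate digestion, fast
insulin absorption, slow insulin absorption, and the recent glucose
trajectory. Combination is staged: a rectified dense layer (width
`combiner_width`, default 8) first merges the three exogenous encoder
states — the processes that jointly set the glucose flux — and a second
rectified dense layer merges that summary with the BG encoder state. A
linear head outputs the predicted *variation* of BG at the next sample
(delta-BG, mg/dL), not the level itself; predicting the increment keeps the
target small, stationary, and tied to the underlying rate equations.

Inputs are windows of `window_span_min` = 540 min (9 h), i.e. W = 36
samples at the 15-min simulated rate or W = 108 at a 5-min CGM rate; the
9-h span covers the support of even slow-insulin action. Each channel is
z-scored with training-set statistics; targets stay in mg/dL.

Multi-step forecasts unroll the one-step model recursively: predict the
delta, form the next level, clamp it to the sensor range [20, 400] mg/dL,
slide the window one sample with the predicted BG and **zeros in the meal
and insulin channels** (future exogenous inputs are unknown at forecast
time), and repeat `horizon/dt` times. The forecast is therefore the
"no further action" trajectory. Appended BG values re-enter the model
through the same training normalization.

### Training

Adam (learning rate 1e-3), batch size 64, mean squared error on delta-BG,
up to 200 epochs with early stopping: a seeded tenth of the training
windows is held out of gradient updates and monitored with patience 20; the
best weights seen are restored. The network is implemented directly in
numpy (float64) with analytic backpropagation through time — the
architecture is small enough (a few thousand parameters) that this trains
in tens of seconds per patient on one CPU — and gradients are verified
against central finite differences in the test suite. Runs are
bit-reproducible from the config seed in single-threaded execution.

## Synthetic cohort simulator

No public dataset is required: the package generates multi-day cohorts
from a minimal kinetic model. Meal and bolus events produce gamma-shaped
rate profiles `amount · t/τ² · exp(−t/τ)` (unit mass, peak at `t = τ`), and
glucose follows

    dG/dt = S_c·Ra(t) − S_i·Ia(t) − k_d·(G − G_b) − k_r·max(0, G − G_r)

where Ra/Ia superpose the active meal/insulin kernels, `k_d` pulls G back
to the basal level `G_b` (endogenous hepatic production below basal,
insulin-independent uptake above it), and `k_r` models renal clearance
above the threshold `G_r` = 180 mg/dL. Integration is explicit Euler at a
1-min internal step, subsampled to the CGM period; the system is not stiff
and the tests confirm agreement with a 0.1-min reference integration to
within 1 mg/dL. G is clamped to the sensor range [20, 400] mg/dL
(saturated readings are a sensor artifact, and the evaluator excludes
saturated reference samples from RMSE by default). Optional i.i.d.
Gaussian CGM noise (default 0) is added after integration.

Per-patient constants are drawn uniformly from documented ranges: basal
90–140 mg/dL, carbohydrate sensitivity 2–4 (mg/dL)/g, insulin sensitivity
30–50 (mg/dL)/U, carbohydrate τ 30–60 min, fast-insulin τ 40–70 min,
slow-insulin τ 240–360 min. The return-to-basal rate `k_d` ∈ [0.015, 0.03]
min⁻¹ and renal rate 0.01 min⁻¹ were fixed by a steady-state balance
argument: with ~180 g carbohydrate and ~30 U insulin per day the net
exogenous drive is hypoglycemic, and `k_d` in this range lets endogenous
production offset it with a mean depression of ~20–45 mg/dL below basal
while still permitting meal peaks toward and above 180 mg/dL. Daily
schedules are randomized independently per day (three meals of 30–90 g
near 07:00/13:00/19:00 with ±60 min jitter, a 2–8 U fast bolus with each
meal, one 10–20 U slow bolus near 22:00), so held-out days carry unseen
input patterns. Events enter the record as impulses — the full amount in
the sample bin containing the event — matching how diary-style logs record
meals and boluses.

What the simulator does *not* emulate: sensor drift and autocorrelated CGM
noise, meal composition and mixed-meal absorption, exercise, stress,
circadian insulin-sensitivity variation, or the person-to-person diversity
of real physiology beyond the sampled constants. Accuracy figures obtained
on this generator therefore bound the method's behavior under clean,
fully recorded conditions; they do not predict clinical performance, which
the real-data path (same CSV schema, 5-min sampling, the two filters
below) exists to measure.

## Dataset protocols

Windows are contiguous with stride 1; a series of length L yields L − W
samples, each labelled with `bg[end+1] − bg[end]`. Two split protocols are
provided: a seeded random 70–30 split over windows, and a by-day split
(first `train_days` days train, remainder validate). Because random-split
windows overlap in time, train and validation windows share samples; the
resulting optimism is inherent to that protocol and is the reason the
by-day split exists alongside it. Real CGM gaps of ≤ 2 samples are filled
by last observation carried forward; longer gaps split the record into
independent segments.

Two data-quality filters handle ambulatory records with incomplete diaries:

- **Unrecorded-meal segments.** Any interval where BG rises by ≥ 50 mg/dL
  (configurable) within 60 min with no meal recorded in the interval or
  the preceding 60 min is flagged, and windows overlapping flagged samples
  are dropped — such rises are almost certainly an unlogged meal and would
  teach the model spurious dynamics.
- **Events inside the forecast span.** Validation windows with a meal or
  bolus strictly inside `(window end, window end + horizon]` are dropped:
  the recursion zeroes future exogenous inputs, so these outcomes are
  unpredictable from the information the model receives.

Both filters are idempotent and configurable; thresholds are package
defaults, not values inherited from any dataset.

## Evaluation

RMSE is `sqrt(mean((G_measured − G_estimated)²))` in mg/dL. Per-horizon
scores use the final step of each recursive trace (the prediction at
exactly the horizon); all-steps scoring is available as an option. Clinical
accuracy uses the Clarke Error Grid with the standard piecewise
boundaries: zone A when the prediction is within 20% of the reference or
both values are ≤ 70 mg/dL; E for opposite-treatment errors (reference
≥ 180 predicted ≤ 70, or reference ≤ 70 predicted ≥ 180); C for
overcorrection regions; D for missed out-of-range events; B otherwise.
The tests verify the boundaries partition the whole positive grid and obey
the 20% rule.

The benchmark protocol (`glucast.protocols.random_split_benchmark`) runs
the full pipeline — 3 patients × 10 days at 15-min sampling, 10 memory
units, seeded 70–30 splits, five seeds — and averages per-patient RMSE and
Zone-A fractions at 30 and 60 min. These sizes keep the whole benchmark in
the minutes range on a single CPU while leaving ~900 windows per patient,
enough for stable RMSE estimates. The memory-unit sweep ({5, 10, 15} ×
{30, 60} min) and the cross-patient transfer test reuse the same
machinery.

## Numerical and design notes

- Forget-gate biases initialize to 1; other weights are Glorot-uniform
  from the config seed. Encoders return final states only — the simplest
  reading of staged combination — rather than full sequences.
- Combiner depth/width and activations (two rectified stages, width 8)
  are package choices; the staged structure, not the exact widths, is the
  design constraint.
- Zero-variance channels (e.g. an all-zero bolus channel after filtering)
  standardize with scale 1 to avoid division by zero.
- Degenerate inputs fail loudly: empty training sets, non-integral
  window/step ratios, shape mismatches and non-finite losses raise with
  context rather than propagating NaNs.

## Known limitations

- The numpy trainer is single-threaded and CPU-bound; it is sized for
  per-patient personalization, not population-scale training.
- Random-split figures overstate generalization (window overlap); use the
  by-day split for honest generalization to unseen days.
- The simulator's simplicity makes simulated forecasts easier than real
  ones; expect substantially higher RMSE on ambulatory data.
- Transfer between patients is evaluated but not mitigated (no pooled or
  fine-tuned training).
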