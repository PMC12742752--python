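# sagru

Short-term blood-glucose forecasting from continuous glucose monitoring
(CGM) traces with a stacked attention-GRU, plus threshold-based adverse-
event detection and the standard clinical evaluation suite.

## The problem

Hospitalized patients with type 2 diabetes wear CGM sensors that record
interstitial glucose every 15 minutes (96 readings/day, stays of 4–14
days). Forecasting glucose 30 and 60 minutes ahead gives clinicians a
window to intervene before a hypoglycemic (< 70 mg/dL) or hyperglycemic
(≥ 180 mg/dL) episode — jointly, *adverse events*. This package implements
that forecaster as a tested, reusable toolkit for researchers working with
15-minute CGM data, together with a seeded synthetic-cohort simulator so
every stage is runnable and testable without access to any clinical data.

## The model

Each input is a 2-hour window of 8 consecutive readings with two features
per step: clock time (decimal hours, scaled by 1/24) and min–max-normalized
glucose, `X′ = (X − X_min)/(X_max − X_min)` with fixed bounds
`[39.6, 500.4]` mg/dL. The target is the glucose 2 steps (30 min) or 4
steps (60 min) past the window, trained per horizon.

The network is a two-layer stacked GRU (32 hidden units) with a
squeeze-and-excitation (SE) attention block after each layer, then a
128→32→1 fully connected head on the last hidden state. The GRU cell:

```
r_t = σ(W_r x_t + U_r h_{t−1} + b_r)          reset gate
z_t = σ(W_z x_t + U_z h_{t−1} + b_z)          update gate
h′_t = tanh(W_h x_t + U_h (r_t ⊙ h_{t−1}) + b_h)
h_t = z_t ⊙ h_{t−1} + (1 − z_t) ⊙ h′_t
```

The SE block squeezes the feature sequence `K` along one axis by global
average pooling, excites through a bottleneck `S = σ(W₂ · ReLU(W₁ Z))`, and
rescales `K′ = S ⊙ K`; the weights `S ∈ (0,1)` are exposed for attention
analysis against time of day and glycemic level. Everything — forward pass,
analytic backpropagation, and the Adam training loop — is implemented in
NumPy and verified against independent elementwise oracles and
finite-difference gradients.

Evaluation covers RMSE / MAE / MARD, canonical Clarke Error Grid zones
A–E, adverse-event accuracy / precision / recall, absolute-error
distribution summaries, and paired t-tests across repeated random
patient-level 6:2:2 splits. An ablation harness compares the plain GRU,
the stacked GRU without attention, and the full model.

## Worked example

```python
from sagru import (SyntheticCohortParams, simulate_cohort, split_patients,
                   SplitSpec, TrainConfig, train_model, variant_factory,
                   windows_from_cohort, evaluate_predictions)
from sagru.pipeline import predict_mgdl, persistence_predictions
from sagru.metrics import rmse

cohort = simulate_cohort(SyntheticCohortParams(n_patients=12, stay_days=(5, 5), seed=7))
train_c, val_c, test_c = split_patients(cohort, SplitSpec(seed=7))
ds_train = windows_from_cohort(train_c, 30)   # 30-minute horizon
ds_val = windows_from_cohort(val_c, 30)
ds_test = windows_from_cohort(test_c, 30)

result = train_model(ds_train, ds_val, variant_factory("sagru"),
                     TrainConfig(epochs=20, batch_size=128, learning_rate=0.01, seed=7))
pred = predict_mgdl(result.params, result.model_config, ds_test)
report = evaluate_predictions(pred, ds_test.targets)
```

Printed for this run:

```
windows: 3297 train / 1413 val / 942 test
30-min test RMSE   12.36 mg/dL   (persistence baseline 13.88)
MAE 8.78 mg/dL   MARD 5.81 %
adverse-event accuracy 81.32 %  precision 56.15 %  recall 66.50 %
Clarke zones: {'A': 901, 'B': 24, 'C': 0, 'D': 17, 'E': 0}
```

After only 20 epochs on a 12-patient cohort the model already beats the
persistence baseline (predicting the last observed value) and places 95.6%
of forecasts in Clarke zone A — clinically benign agreement. Longer
training on larger cohorts tightens all of these (see below).

The same stages are available from the shell:

```
sagru simulate --out sim/ --n-patients 40 --seed 1
sagru train sim/cohort.csv --out run/ --variant sagru --horizon 30 --epochs 50
sagru evaluate run/checkpoint.npz sim/cohort.csv --out eval/ --horizon 30
sagru ablate sim/cohort.csv --out ablation/ --repetitions 10
```

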