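# Methods

This note records the modeling choices, parameter conventions, and known
limitations behind the package, in the order data flows through it.

## Data model and exclusion rules

A patient series is an ordered list of (timestamp, glucose mg/dL) readings
at a nominal 15-minute cadence. Glucose supplied in mmol/L is converted on
ingestion by the factor 18.0 mg/dL per mmol/L — the only factor consistent
with the standard clinical threshold pairs (3.0 mmol/L ↔ 54 mg/dL,
10.0 mmol/L ↔ 180 mg/dL). A patient is excluded outright when the trace
contains a recording interruption longer than 1 day or any reading that is
0 or outside [39.6, 500.4] mg/dL; these bounds double as the normalization
range and are configurable, since "extreme outlier" has no universal
numeric definition. Shorter gaps do not exclude: they split the trace into
contiguous segments, and windows never span a segment boundary. Sensor
clock jitter is tolerated up to 90 s when testing whether two readings are
"15 minutes apart"; this, too, is configurable.

## Preprocessing

Clock time is encoded as decimal hours (11:30 → 11.5) and divided by 24
before entering the model, the minimal analogue of the glucose min–max
normalization; the unscaled decimal hour is retained for reporting.
Glucose is normalized by `(x − 39.6)/(500.4 − 39.6)`; the inverse is exact
to machine precision. Supervised pairs use 8-step (120-min) windows at
stride 1 with the target 2 or 4 steps ahead (30/60 min at the 15-min
cadence); for a segment of N readings this yields
`max(0, N − 8 − h + 1)` windows. Targets stay in mg/dL at the interface;
the training loss operates on normalized targets and predictions are
denormalized before any metric is computed, because the error metrics are
defined in mg/dL.

## Network

Default architecture: GRU(32) → SE → GRU(32) → SE → FC 128 → FC 32 → FC 1,
on 2-feature inputs. Design points that were genuinely open:

- **Candidate recurrence.** The candidate state uses the standard
  formulation `h′ = tanh(W_h x + U_h (r ⊙ h_prev) + b_h)` with a learned
  recurrent matrix `U_h`. A `literal_eq3` flag drops `U_h` and applies the
  reset-gated hidden state additively; that variant is dimensionally
  degenerate as a learned layer and exists only for comparison.
- **Biases** are included in all gates (standard practice); a `use_bias`
  flag zeroes them.
- **Sequence collapse.** The FC head reads the last step's hidden vector
  (32 → 128). A `fc_input="flatten"` alternative feeds the full 8×32
  sequence (256 → 128).
- **SE axis.** `se_axis="channels"` (default) pools over the 8 time steps
  and learns one weight per hidden channel; `se_axis="steps"` pools over
  channels and learns one weight per time step, the view used for
  per-time-point attention summaries. The two SE blocks do not share
  parameters. The pre-attention transform is the identity: the GRU output
  itself is the feature map being reweighted (there is no convolutional
  front-end in this 1-D setting).
- **SE reduction** defaults to r = 4 (bottleneck 8 for 32 channels, 2 for
  8 steps). With these defaults the full model has 19,009 parameters.
- One model is trained per horizon; the head emits a single value.

Weights initialize uniformly in ±1/√hidden from a seeded generator;
biases start at zero. The forward pass, the analytic backward pass, and
Adam are implemented directly in NumPy. Correctness is established two
ways: every layer and the full pass are tested against independent
elementwise (pure-Python-loop) implementations of the gate and attention
equations at 1e-8 or better, and the backward pass is checked against
central finite differences at 1e-7 across all architecture variants.

## Events and metrics

Glucose < 70 mg/dL is hypoglycemic; ≥ 180 mg/dL hyperglycemic (70 itself
is normal, 180 itself is hyperglycemic — consistent with the "≥ 180"
clinical convention; both thresholds and the strictness at 180 are
configurable). Events are binary adverse-vs-normal, pooling hypo and
hyper; the three-way label remains available. Precision or recall with an
undefined denominator is reported as missing, never coerced to zero.

RMSE, MAE and MARD follow their standard definitions with MARD in percent
of the reference. Clarke Error Grid zones implement the canonical 1987
piecewise boundaries; line comparisons are kept in integer-scaled form
(e.g. `5y ≤ 7x − 910` rather than `y ≤ 1.4x − 182`) so lattice points on
a boundary land deterministically, and the implementation is tested
against a separately written region-membership oracle on every integer
point of [1, 550]². Absolute-error summaries use linearly interpolated
quantiles and the n−1 standard deviation. Repeated-run comparisons use
the two-sided paired t-test; a zero-variance difference raises a
degenerate-case error rather than returning a misleading statistic.

## Training and experiments

Splits are patient-level 6:2:2 by largest-remainder apportionment of the
shuffled patient list (196 patients → 118/39/39; 109 → 65/22/22), with
disjointness asserted on every split. Training defaults mirror the
reference setup — Adam, batch 512, learning rate 0.001 — with a desk-scale
default of 50 epochs (500 by config). The loss is MSE on normalized
glucose, consistent with RMSE as the headline metric (MAE available);
returned parameters are best-on-validation (last-epoch mode available).
An optional step schedule multiplies the learning rate at listed epochs;
the learning-sanity and acceptance runs use batch 128, rate 0.01 with ×0.3
decay at epochs 30 and 42, which reaches the noiseless configuration's
sub-1-mg/dL floor within the 50-epoch budget. `run_experiment` derives
repetition k's split and training seeds from `seed + k`, making the whole
experiment a pure function of (cohort, config, seed); it aggregates every
metric as mean ± SD and runs paired t-tests of the full model against each
ablated variant. Repetitions are independent random re-splits, not
cross-validation folds.

## Synthetic cohort

The simulator emulates the *shape* of an inpatient CGM study: 96
readings/day, stays 4–14 days, fixed hospital meal schedule (07:00, 11:30,
17:30), per-patient baseline (145 ± 25 mg/dL), a mild circadian sinusoid
(±10 mg/dL), post-meal excursions (peak ~60 ± 15 mg/dL, 30-min linear rise
then 90-min exponential decay), stationary AR(1) noise (ρ = 0.9, SD
5 mg/dL) giving the short-range smoothness of real CGM traces, and
nocturnal hypoglycemic episodes (15% of nights, 00:00–04:00) that pull
glucose toward a ~58 mg/dL nadir with a Gaussian time profile. Values are
clipped to [39.6, 500.4]. Episode uniforms are drawn for every night
regardless of the rate, so raising the rate only adds episodes at a fixed
seed. Everything is a pure function of the parameter set including its
seed, with per-patient streams spawned from the master seed.

The `noiseless()` configuration (no noise, no episodes, shared meal
amplitudes) makes the future an exact function of the last observed
glucose and the clock, giving the optimizer a ground-truth target it can
drive below 1 mg/dL RMSE.

What the simulator does **not** model: insulin–glucose physiology
(no Bergman/UVA-Padova dynamics), sensor lag, meal-time variability,
treatment responses, or the heavy-tailed artifacts of real sensors.
Passing tests on this cohort therefore demonstrate that the pipeline
learns genuine temporal structure and that every computation is correct
and reproducible — not that the model reaches any particular accuracy on
real clinical data.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
cohorts of 10–40 patients with 4–7-day stays, 50 training epochs, one CPU.
The repeated-experiment checks use 10 repetitions at 2 epochs — enough to
exercise splitting, aggregation and testing logic, which do not depend on
convergence.

## Known limitations

- A printed parameter total of 31,557 reported for this architecture
  elsewhere is not reproducible under any standard accounting of the
  layer table (plausible configurations give ≈19k–47k); the default here
  has 19,009 parameters and the count is tested, not assumed.
- Training is CPU NumPy: ~1 s per epoch on ~16k windows. Fine for study
  cohorts of tens of patients; hundreds of patients at 500 epochs would
  want a GPU framework.
- Event detection inherits the single-point threshold rule; no episode-
  level (duration-based) event definition is implemented.
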