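# Methods

`vibrofeed` quantifies the collective feeding intensity of largemouth bass
(*Micropterus salmoides*) from water-surface vibration, forecasts it 5 s
ahead, and uses the forecast to stop a feeder before feed is wasted.  No
public recording of the underlying triaxial sensor data exists, so the
package pairs the analysis pipeline with a calibrated synthetic generator
that reproduces the published summary statistics of the four factorial
feeding experiments.  This note records the models, the calibrations, and
the design choices that were genuinely open.

## Signal model

A floating triaxial sensor reports signed displacement `x, y, z` (μm) at
`fs = 10 Hz`.  Three operations turn this into a feeding-intensity signal:

1. **Amplitude gate.** Samples with `|d| < δ` are zeroed per axis.  The gate
   removes aeration-bubble noise, which is bounded below the threshold by
   construction.  `FilterConfig.threshold_um` defaults to the sensor-scale
   value 500 μm (0.5 mm); the synthetic traces live at a ~1000× smaller
   per-sample scale (see *Units*, below) and use the scale-matched gate
   `GeneratorParams.gate_um = 0.5 μm`.
2. **Triaxial sum.** `s_i = |x_i| + |y_i| + |z_i|`, gating first.  The strong
   inter-axis correlations (about 0.9) justify summing magnitudes rather
   than picking one axis: all three axes carry nearly the same feeding
   signature, and summation amplifies it against axis-local noise.
3. **Windowing.** Non-overlapping 5-s windows (50 samples) accumulate
   `D_sum[k] = Σ s_i` and the max wave height `H_max[k] = max s_i`.  An
   incomplete trailing window is dropped rather than padded, which would
   otherwise bias the final window low.

**Units.** The published peak *window sums* sit in the hundreds of μm while
the published gate is 0.5 mm per *sample* — mutually inconsistent scales for
a 150-term sum of magnitudes.  The package treats the window-sum scale
(which anchors every regression it must reproduce) as authoritative and
scales the gate and bubble noise of the synthetic world to match, keeping
the ~0.6 bubble/gate ratio.  The gate semantics are unaffected; only the
default magnitudes differ between the sensor-scale and synthetic-scale
configurations.

## Synthetic trial generator

One trial simulates a feeding session for a condition
`(S g fish mass, D fish, V g/s feed rate, Φ mm pellet diameter)` over
`duration_s` (default 120 s).

**Deterministic core.** A gamma-shaped burst envelope

    A(t) = A_peak · (t/t_peak)^κ · exp(κ(1 − t/t_peak)),   κ = 6

peaks at `t_peak(V) = 42.5 − 7.5·V` seconds (clamped inside the trial), the
line through the two published timing observations (≈35 s at 1 g/s, ≈20 s at
3 g/s).  κ = 6 gives a burst sharp enough that the peak 5-s window is
unambiguous at window cadence for every oscillation phase; flatter shapes
(κ ≲ 3) let the phase of the within-window oscillation move the argmax by a
full window.  A pellet-grade oscillation `1 + m·sin(2πf t + φ)` with
`m = 0.6` and `f = 2.0 Hz × {1.0, 0.58, 0.75}` for 2#/4#/6# pellets
modulates the envelope; the 2#→4# factor 0.58 encodes the published 42%
frequency reduction, the other factors are package defaults.  `m = 0.6` is
large enough that the mean-crossing detector sees the oscillation across the
whole active burst (frequency recovery), small enough that window sums stay
calibration-dominated.

**Amplitude calibration.** `A_peak` is chosen per trial so the *noiseless*
maximum window sum equals `mean_peak(config)` exactly.  `mean_peak` comes
from two absolute per-experiment calibrations: for each of the size and
density experiments, the three group means are the unique solution of a 3×3
linear system requiring (a) equal-weight OLS through `(level, mean)` to
return exactly the published slope and intercept and (b) the top/bottom
ratio to equal the published percent increase.  The solutions do not lie on
the regression lines — consistent with the published R² < 1 — and resolve
the apparent tension between the printed lines and printed ratios.  The two
experiments imply different absolute levels at their common anchor
(S=50 g, D=30, V=1 g/s, 4#); each experiment is authoritative within its own
baseline, and any other condition uses a reference-normalized multiplicative
combination `μ_size(S) · μ_dens(D)/μ_dens(30)` anchored there.  Feed rate
moves peak *timing*, pellet grade moves *frequency*; neither scales
amplitude.

**Noise.** Three seeded components:

* a common multiplicative AR(1) factor `max(0, 1 + cv·F_t)` with `cv = 0.15`
  and lag-1 coefficient 0.5, shared by all axes (session-to-session
  variability of the collective response);
* axis *shares*: the three axes receive fractions `π_i(t) = 1/3 + d_i(t)` of
  the total signal with `Σ d_i = 0` exactly, where `d` is a 3-variate AR(1)
  with a singular covariance solved per trial so that the raw per-axis
  Pearson correlations equal (ρXY, ρXZ, ρYZ) = (0.93, 0.88, 0.91).  Because
  the shares sum to one, the summed signal — and hence every window-sum
  statistic the amplitude calibration controls — is untouched by this
  component.  The solve uses the exact time-moments of the trial's
  deterministic part and the analytic moments of the clipped noise factor;
  it is a 3-unknown root find, feasible whenever bubble noise alone does not
  cap the correlation below the largest target (checked, with a clear error
  otherwise).  A naive one-factor multiplicative construction cannot reach
  these correlations: the shared envelope already forces per-axis raw
  correlations above ≈0.95 at realistic noise levels;
* additive bubble noise, uniform `±0.1 μm` per axis, strictly below the
  0.5 μm gate so the gate provably removes it.

`noiseless=True` switches all three off (the oscillation phase stays
seeded), giving the analytic test mode used by the exact-recovery checks.

The one-factor loading solve `w_x = √(ρXY·ρXZ/ρYZ)` (etc.) is exposed as
`factor_loadings` for constructing correlated Gaussian triples and is tested
against its closed form; the generator itself uses the share construction
above for the reasons stated.

**Dataset.** The default design replicates the four factorial experiments —
size {50,150,300} g, density {20,40,60}, rate {1,2,3} g/s, pellet {3,5,7} mm,
each with the other factors at the Table-level baseline — at 34 replicates
per condition, totalling 408 trials.  Per-trial seeds spawn deterministically
from one master seed.

**What the generator does and does not emulate.** It reproduces the
published group means, regression lines, percent increases, peak timing,
inter-axis correlations and the pellet frequency effect, with plausible
burst dynamics and noise.  It does not model hydrodynamics, individual fish,
tank geometry, non-stationary backgrounds, sensor drift, or any
cross-factor interaction beyond the multiplicative combination rule.  Tests
passing on this data show the pipeline recovers what the generator encodes;
they are not evidence about live-fish signals.

## Characterization

Peak displacement is the maximum window sum (earliest window on ties, for
determinism); peak time is that window's midpoint, so a timing check can
never be sharper than ±2.5 s.  Response fits are closed-form equal-weight
OLS with intercept, `R² = 1 − SS_res/SS_tot`.  Percent increases are defined
on group means.  "Fluctuation frequency" is operationalized as the
mean-crossing rate: remove the series mean, count sign changes `c` (zeros
attach to the previous sign), frequency `= c/(2T)`.  On a burst signal the
long quiet tails dilute this rate, so frequency recovery is evaluated on the
*active segment* (samples ≥ half the maximum), where the modulation depth
guarantees crossings throughout; the ratio between pellet grades is
insensitive to this choice.

## Forecasting

Supervised samples pair a 50-step context of per-step features
`[s_i, t_i, S, D, V, Φ]` (statics broadcast per step) with either the next
window's sum (scalar mode) or the next 50 per-sample sums (trajectory mode,
consumed by the controller).  Features and targets are z-scored (sample sd,
ddof=1) with statistics fitted on the training split only; metrics are
reported on the de-normalized μm scale.  The 80/20 split is random by sample
by default, with a by-trial option for leakage studies.

The forecasters are implemented in a self-contained numpy reverse-mode
autodiff engine (`vibrofeed.nn`): a stacked 2×128-unit tanh LSTM (forget
bias 1) with 0.2 dropout, a dense-64 ReLU layer and a linear head; a GRU of
the same shape; and a 2-block single-head Transformer encoder (model width
128, feed-forward 256, sinusoidal positional encoding, last-token readout).
Training uses Adam (lr 0.001), batch 32, MSE loss, early stopping with
patience 20 restoring best-validation weights, everything seeded.  All
gradients are verified against numerical differentiation in the test suite.

**Problem sizes.**  Training runs in this package are desk-scale CPU runs:
supervised windows are built at stride 10–12 rather than 1, the training
split is capped at 2500–3000 samples, and epochs at 10–12.  On this
synthetic data the scalar LSTM reaches held-out R² ≈ 0.99 within those
budgets (the irreducible window-sum noise at the default settings caps R²
near 0.997), so longer schedules buy nothing.  Architecture, optimizer,
batch size and loss are never scaled.

## Closed-loop control

The controller replicates the deployed decision rule exactly: a rolling
50-sample buffer; every 5 s a trajectory forecast of the next 50 per-sample
sums; a *decline* when `mean(pred[25:50]) < 0.9 · mean(pred[0:25])`
(strict); a non-decline resets the counter; two consecutive declines latch a
stop.  A proportional 0–255 drive signal (forecast window sum over the
running session maximum, round half up) is logged as an optional output
mode; the stop rule alone controls the feeder.

Sessions run against an invented, fully configurable satiation tank:
capacity `0.015·S·D` grams (1.5% of biomass), maximum intake
`0.5·D` g/s scaled by appetite `max(0, 1 − consumed/capacity)`, and the
feeding-vibration envelope scaled by current appetite.  With the default
300 g × 30-fish condition and a 2 g/s feeder these values mean hungry fish
clear the delivery for about the first minute, while the forecast decline of
the feeding burst stops the feeder at 50–55 s — so the stop is anticipatory
(appetite ≈ 0.2 at stop) and the residual-feed rate is ~0%.  The residual
feed bound demonstrated by the closed-loop tests is a property of this
surrogate tank, not a claim about live fish.  A trajectory model trained on
open-loop trials smooths the within-horizon slope, so decline flags follow
the envelope's shape rather than the appetite sag; the tank defaults leave a
±20 s stop-time margin rather than balancing on a knife edge.

## Numerical choices and degenerate inputs

* Peak ties break to the earliest window; proportional output rounds half up.
* Zero-variance features and targets raise explicit errors (never silent
  division); constant static columns in a homogeneous training set are given
  unit scale instead.
* The share-covariance root find rejects infeasible targets (non-PSD
  covariance, negative share variance, bubble-capped correlation) with
  specific errors; the solver is judged by its residual, not its status flag.
* Trials shorter than one analysis window, empty window series, non-monotone
  trace timestamps and non-finite samples are rejected with descriptive
  errors; a series shorter than one window yields an empty `WindowSeries`
  with a warning.
* Generated axis magnitudes are non-negative by construction (plus signed
  bubble noise); the processing chain rectifies anyway, so signedness does
  not affect any downstream statistic.

## Known limitations

* Cross-condition amplitudes outside the two calibrated baselines rest on an
  invented multiplicative combination; only the per-experiment profiles are
  anchored to published values.
* The 6# frequency factor, envelope shape, modulation depth, noise level and
  AR coefficients are package defaults, not published values.
* The satiation tank is a control-demonstration surrogate; its parameters
  were chosen so the default demonstration is robust, and different tanks
  can make the same controller fail.
* The Transformer baseline underperforms the recurrent models at these data
  sizes; the comparison table records, and is not meant to settle, the
  architecture question.
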