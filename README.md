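# vibrofeed

Vibration-based quantification and predictive control of feeding intensity
for largemouth bass (*Micropterus salmoides*) aquaculture.

Collective feeding in a stocked tank agitates the water surface.  A floating
triaxial sensor turns that agitation into displacement series `x, y, z` (μm,
10 Hz), and the vigor of feeding — the quantity a feeder controller needs —
is proxied by the gated triaxial magnitude sum accumulated over 5-s windows:

    s_i     = |x̃_i| + |ỹ_i| + |z̃_i|          (per-axis amplitude gate δ, then sum)
    D_Σ[k]  = Σ_{i ∈ window k} s_i             (50 samples = 5 s at 10 Hz)

A sequence model (stacked LSTM; GRU and Transformer baselines) forecasts
`D_Σ` five seconds ahead from a 50-step context of
`[s_i, t_i, S, D, V, Φ]` — the live signal plus fish mass `S` (g), stocking
density `D` (fish/tank), feed rate `V` (g/s) and pellet diameter `Φ` (mm).
A stop-feeding controller watches the forecast trajectory: when its
second-half mean falls below 0.9× its first-half mean in two consecutive
5-s cycles, the feeder stops — before uneaten feed accumulates.  Closed-loop
sessions are scored by the residual feed rate,
`RFR = residual feed mass / total feed mass × 100%`.

The package is aimed at precision-aquaculture researchers and engineers who
want to study or extend this control strategy without the hardware: since no
raw recordings are publicly available, it ships a seeded synthetic generator
whose trials are calibrated to the published relationships — the peak-
displacement regressions against fish size (`Y = 1.7316·S + 236.41`) and
density (`Y = 5.4250·D + 47.11`) together with their 109.7%/141.9% group
contrasts, feed-rate-dependent peak timing (≈35 s at 1 g/s, ≈20 s at
3 g/s), inter-axis correlations (0.93, 0.88, 0.91) and the 42% pellet-
palatability frequency reduction.  See `docs/methods.md` for the model and
calibration details.

## Worked example

```python
import numpy as np
from vibrofeed import (TrialConfig, FilterConfig, generate_trial, triaxial_sum,
                       window_sums, peak_displacement, peak_time,
                       interaxis_correlation)

cfg = TrialConfig(size_g=300, density=30, feed_rate=2, pellet_mm=5, seed=42)
trace = generate_trial(cfg)                      # 120 s seeded trial
s = triaxial_sum(trace, FilterConfig(0.5))       # gate + magnitude sum
ws = window_sums(s)                              # 5-s windows
peak, k = peak_displacement(ws)
corr = interaxis_correlation(trace)
print(f"peak window sum: {peak:.1f} um in window {k} (t = {peak_time(ws):.1f} s)")
print(f"inter-axis correlations: rho_xy={corr.rho_xy:.3f} "
      f"rho_xz={corr.rho_xz:.3f} rho_yz={corr.rho_yz:.3f}")
print("window sums (um):", np.array2string(ws.d_sum[:12], precision=1))
```

prints

```
peak window sum: 804.5 um in window 5 (t = 27.5 s)
inter-axis correlations: rho_xy=0.929 rho_xz=0.906 rho_yz=0.917
window sums (um): [  0.    9.5 166.9 455.6 679.2 804.5 737.4 564.6 394.  278.5 154.7  71.3]
```

The burst peaks in the window containing `t_peak(V=2) = 27.5 s`; the peak
window sum fluctuates around the calibrated 792.5 μm expectation for the
300 g condition, and the raw axes correlate near the (0.93, 0.88, 0.91)
targets.

The same stages are scriptable from the shell:

```
vibrofeed simulate    --n-per-condition 1 --seed 3 --out runs/sim
vibrofeed characterize --experiment size --n-per-level 6 --seed 0 --out runs/chz
vibrofeed train       --arch lstm --mode scalar --seed 0 --out runs/model
vibrofeed control-sim --model runs/model --out runs/ctl
```

`characterize` writes a per-level CSV and a JSON summary (slope, intercept,
R², top-vs-bottom percent increase); `control-sim` writes per-session command
logs and the aggregate RFR.

## Layout

```
src/vibrofeed/
  signal_processing.py   gating, triaxial summation, windowing, z-scoring
  synthetic.py           calibrated seeded trial/dataset generator
  characterization.py    peaks, OLS response fits, frequency analysis
  nn.py                  numpy autodiff + LSTM/GRU/Transformer + Adam
  forecasting.py         supervised windows, training, metrics, comparison
  control.py             decline detector, stop logic, satiation tank, sessions
  io.py, cli.py          trace/manifest/model artifacts and the CLI
```
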