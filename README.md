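# icebear

Behavioral analysis of polar bear telemetry on drifting sea ice: wind-forced
ice-drift correction, a four-state menotactic hidden Markov model with
environmental covariates, state decoding, and spatial dominant-state
mapping — packaged with a synthetic study system so the whole pipeline is
testable end to end without any external data.

## Who it is for

Movement ecologists working with GPS collar data from animals on a moving
substrate (sea ice, water currents), where the observed track mixes
voluntary movement with passive transport and where behaviors are oriented
relative to an external stimulus such as wind.

## The model

Tracks (2-h fixes, km on a projected plane) are reduced to step speeds
`l_t` and turning angles `φ_t`. A four-state HMM — drift `D` (stationary on
moving ice), area-restricted search `ARS`, and olfactory search `O(L)`/`O(R)`
biased left/right of the wind — generates

* `l_t ~ gamma(μ_S, σ_S)` with `μ_D = β₁ + β₂ r_t^(tide)` (the drift state
  rides the tidal current),
* `φ_t ~ von Mises(μ_S^(φ), κ_S)` where the mean turn trades directional
  persistence against bias relative to a stimulus,
  `μ^(φ) = atan2(α₁ sin ψ + α₂ cos ψ, 1 + α₁ cos ψ − α₂ sin ψ)` — the tide
  for `D`, the wind for the olfactory states (mirrored between `O(L)` and
  `O(R)`), and `μ^(φ) = 0` for `ARS`,
* multinomial-logit transition probabilities that are linear, quadratic or
  cosinor (hour-of-day) functions of environmental covariates, with
  forward/backward stepwise AIC selection.

Each biased state is summarized by the scaled magnitude of attraction
`M* = √(α₁²+α₂²) / (1+√(α₁²+α₂²)) ∈ [0,1)` (0 = pure correlated random
walk, 1 = fully stimulus-driven) and the attraction angle
`ϑ = atan2(α₂, α₁)` relative to the stimulus.

Before fitting, wind-forced ice drift is removed: a biased correlated
random walk calibrated on passively drifting "dropped collars" (predictor
chosen by AIC among candidate flow fields) predicts the wind-driven drift
velocity of each step, which is subtracted. Decoded states are rarefied to
bear days on a 50-km grid and mapped by the cell-dominance statistic
`argmax_S (N_i^(S)/N_i) / (N^(S)/N)`, with utilization-distribution
isopleths from a kernel density estimate on daily-thinned positions.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/02_behavior_hmm.py` simulates six bears from the model, runs the
preprocessing pipeline and refits the HMM:

```
log-likelihood -9313.6, AIC 18667.2, 4200 steps
state   mean step (km/h)   sd      kappa
D         0.63             0.30   3.89 (at median tide 0.29 km/h)
ARS       0.79             0.62   0.60
O         2.03             0.92   4.46
olfactory wind bias: M* = 0.242, theta = 92 deg (simulated 0.233 and 92: travel roughly crosswind)
stationary distribution (D, ARS, OL, OR): [0.335 0.313 0.176 0.176]
Viterbi agreement with the simulated states: 75% (states overlap in speed, so decoding is imperfect by construction)
```

The fitted emission parameters recover the generator settings (drift mean
0.63 km/h at the median 0.29 km/h tide, ARS 0.76, olfactory search 2.04),
and the olfactory bias statistics place that state on the BCRW part of the
spectrum: a weak attraction (`M*` ≈ 0.23) at ≈ 92° to the wind — crosswind
travel, the geometry that maximizes odor-plume encounter.

`examples/01_drift_correction.py` calibrates the drift model on simulated
dropped collars (ratio 0.0200 vs the simulated 0.02, deflection 14.9° vs
15°, hourly wind beating a daily-averaged predictor by ~9600 AIC) and
removes 99.9% of a stationary drifter's net displacement.
`examples/03_state_maps.py` builds dominant-state maps, seasonal subsets
and 80% utilization-distribution areas from decoded tracks.

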