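# Methods

This note documents the models implemented in `icebear`, the choices made
where the design was genuinely open, and what the synthetic study system
does and does not establish.

## The movement model

Telemetry is analyzed as step series on a local projected plane (km).  For a
fix interval of Δt hours, step *t* carries a step speed `l_t` (km/h; the
distance between consecutive fixes divided by Δt) and a turning angle
`φ_t ∈ (−π, π]` (counter-clockwise positive; the first turn of a bout is
undefined and contributes only its step-speed density).  Observations are
generated by a four-state hidden Markov model with states

* **D** — drift: the animal is stationary on moving sea ice,
* **ARS** — area-restricted search: slow, tortuous localized search,
* **O(L)/O(R)** — olfactory search biased left/right of the wind.

Step speeds are gamma distributed with state-specific mean μ and standard
deviation σ (shape μ²/σ², rate μ/σ²).  The drift state's mean is
`β₁,D + β₂·r_tide` with `r_tide` the tidal current speed (km/h), on the
identity link with a floor of 1e-6 km/h — the coefficients are unrestricted
real numbers, so the floor keeps the density proper in pathological corners
of the search space (a log link is not provided because the identity link is
the form being exercised).

Turning angles are von Mises with state-specific concentration κ.  The mean
turn trades directional persistence (weight 1) against bias relative to a
stimulus whose direction relative to the previous bearing is ψ:

    μ_φ = atan2(a₁ sin ψ + a₂ cos ψ, 1 + a₁ cos ψ − a₂ sin ψ)

with `a₁` the along-stimulus weight and `a₂` the weight 90° anti-clockwise
of it.  Drift uses the tide as stimulus with `a₁ = α₁,D · r_tide` and no
cross-tide term; ARS has mean turn fixed at 0; the olfactory states use the
wind with shared `α₁` and mirrored `α₂` (O(R) flips the sign), and share
every other parameter, including all transition parameters.  The derived
statistics `M* = |α|/(1+|α|) ∈ [0,1)` (position on the CRW–BRW spectrum) and
`ϑ = atan2(α₂, α₁)` (bias angle relative to the stimulus) summarize each
biased state.

Transitions follow a multinomial logit with the diagonal as reference.  The
twelve off-diagonal entries collapse to seven free slots through the
olfactory symmetry (D→O(L) = D→O(R), identical O rows, symmetric O(L)↔O(R)
exchange).  Each slot's log-odds is a linear function of covariates in one
of three forms: linear, quadratic, or a cosinor pair
(cos 2πh/24, sin 2πh/24) for hour of day.  Linear/quadratic covariates are
centered and scaled by their pooled sample mean/sd; the constants are stored
in the fit so coefficients can be mapped back.  The initial distribution of
each bout is the stationary distribution of the transition matrix at the
bout's first covariate row (the chain is assumed to have been running under
similar conditions before observation began).

### Fitting

The pooled forward log-likelihood (scaled recursion; numba-compiled inner
loop) is maximized by L-BFGS-B on a working scale: log transforms for σ and
κ, and the ordering μ_D < μ_ARS < μ_O enforced by cumulative positive
increments (μ_ARS = μ_D + e^δ₁, μ_O = μ_ARS + e^δ₂) — a monotone transform
with the same constraint semantics as pseudo-design-matrix working
boundaries.  Gradients are structured finite differences: emission partials
rebuild only the affected emission-density columns and transition partials
only the logit matrices, which makes large fits tractable on one core.
Starting values are data-driven (step-speed quantiles, mild persistence),
with seeded jittered restarts (default 3).  Since negating α₂ is an exact
relabelling of O(L)/O(R), fits are canonicalized to α₂ ≥ 0.  The covariance
of the working parameters is the inverse central-difference Hessian;
confidence intervals for stationary probabilities use the delta method
propagated through the stationary solve.  Decoding is by the Viterbi
algorithm.

## Drift correction

Passive "dropped collar" tracks record pure ice drift.  A single-state BCRW
with the same emission family as the HMM links drifter steps to a candidate
flow field: step speed ~ gamma with mean `intercept + slope · flow_speed`,
turn ~ von Mises around the persistence/bias blend above with the flow as
stimulus.  Candidate predictors (e.g. hourly wind vs a temporally averaged
copy standing in for daily ice-motion products) are ranked by AIC and the
winner predicts the wind-driven drift velocity of each bear step, which is
subtracted from the displacement before positions are rebuilt from the
first fix.  The subtracted vectors are stored with the corrected track, so
the correction is exactly invertible.  Tidal motion is deliberately *not*
subtracted: it is absorbed into the drift state's emissions (the tidal slope
on the step mean and the tide-biased turn), because the 12-h rotary tide
cannot be calibrated from 4-h drifter data.  The first step of a track has
no previous bearing; its predicted drift direction falls back to the flow
direction rotated by the fitted bias angle (one step out of hundreds — the
effect is negligible and documented rather than modelled).

## Preprocessing

Tracks are split into bouts wherever the span of *missing* fixes exceeds
6 h (with the 2-h nominal interval, more than three consecutive missing
fixes; the consecutive-fix time difference is then > 8 h).  Bouts spanning
< 24 h or with fewer than eight locations are dropped.  Remaining gaps (≤ 3
fixes) are interpolated either linearly or by a continuous-time correlated
random walk: a Kalman smoother on an integrated Ornstein–Uhlenbeck velocity
(parameters by maximum likelihood; β → 0 degenerates exactly to the
integrated random walk, so a constant-velocity track is reproduced exactly
in the zero-process-noise limit).  Zero-length steps receive a seeded
uniform jitter on (0, 1 m] because the gamma density excludes zero.
Gridded covariates are interpolated bilinearly in space and linearly in
time at each step's starting fix; hour of day is local standard time
(UTC−5), and sun altitude comes from a standard low-precision solar-position
formula (declination/equation-of-time Fourier series; accuracy ~0.2°, ample
for a behavioral covariate).

## Covariate selection

For each candidate the allowed forms are fitted alone and the lowest-AIC
form kept (hour: cosinor only; ordinal date, sun altitude, wind speed,
solar radiation, ice concentration: linear and quadratic; anything else
linear).  Covariates correlated above |r| = 0.5 compete pairwise, resolved
greedily in descending |r| toward the lower-AIC member.  The final set is
chosen by forward and backward stepwise AIC run independently; both results
are reported along with whether they agree.  Ties within 2 AIC go to the
simpler model, which with 7 parameters per covariate block is a mild
simplicity margin.

## Spatial analysis

Decoded steps are rarefied to unique (50-km cell, bear, date, state) "bear
days"; the grid is anchored at the data bounding box's lower-left corner.
The dominant state of cell *i* maximizes `(N_i^S / N_i) / (N^S / N)` — the
within-cell share relative to the overall share — so locally
over-represented rare states are visible; ties go to the smaller state
index.  Cells with fewer than 7 bear days are masked and cells with fewer
than 21 flagged low-confidence.  Subset maps recompute the statistic with
subset totals for early (Jan–Mar) vs late (Apr–Jun) winter, low vs high
mean-ice years (years at or above the across-year mean count as high), and
the youngest vs oldest half of the bears.  Utilization distributions are
plain bivariate Gaussian KDEs (Scott bandwidth) on daily-thinned positions;
thinning stands in for the autocorrelation adjustment of track-aware
estimators, which is adequate for a descriptive area comparison.  The
reported region is the smallest-density isopleth containing the requested
mass, returned as an area and a polygon (union of grid cells).

## The synthetic study system

The simulator generates exactly the structures the analysis assumes: a
spatially uniform tidal field rotating counter-clockwise through 360° every
12 h at 0.29 km/h (the median tidal speed of the study system); wind as a
constant mean vector plus Gaussian-smoothed space-time noise (defaults
25 km/h ≈ 7 m/s mean, 8 km/h component sd, 12-h/300-km correlation scales
— mid-latitude winter values; the field is rescaled so its mean speed is
the requested one); passive drifters at 2% of wind speed deflected 15° to
the right; and bear tracks drawn step by step from the four-state model
with emission values matching the fitted Hudson Bay model (step means
0.63/0.76/2.04 km/h with the drift mean evaluated at the median tide, sds
0.31/0.59/0.93, concentrations 3.64/0.62/4.28, olfactory bias 92° to the
wind).  Missingness is generated in runs (~7% by default).  Ground truth
(states and the exact voluntary/drift displacement split) is recorded, and
observed displacement equals voluntary + drift to machine precision.

What the simulator does *not* emulate: measurement error on fixes, ice-floe
mechanics or realistic meteorology, behaviors outside the four states
(e.g. swimming), and individual heterogeneity (all animals share one
parameter set, as the analysis assumes).  Passing recovery tests therefore
establishes the correctness and internal consistency of the estimators
under the assumed generative model, not robustness to the ways real
telemetry violates it.

## Problem sizes and numerical choices

Test problem sizes were chosen as the smallest that make the statistical
checks sharp: the full-scale emission recovery uses 20 tracks × 2000 steps
(the scale of a multi-year collar program) with tolerances of 5% on means,
15% on concentrations and 5° on the bias angle; stepwise-selection recovery
uses 5 tracks × 700 steps with strong effects (|coefficient| ≈ 1 sd);
drift-model recovery uses 5 drifters × 2000 steps.  Likelihood correctness
is checked against explicit path enumeration at T ≤ 6 and emission densities
against quadrature.  Optimizer: L-BFGS-B, maxiter 500 (reduced with warm
starts inside stepwise selection), structured finite-difference gradients
with step 1e-6; Hessian step 1e-4.  Stationary distributions solve the
linear system by least squares with the normalization row appended;
reducible chains are rejected.  Degenerate inputs (all-zero flow, collinear
point sets, chains with absorbing states) are flagged or rejected rather
than silently handled.

## Known limitations

* Drift-estimation uncertainty is not propagated into the HMM (the
  correction is a point prediction).
* The identity-link tidal step mean can require flooring for extreme
  parameter values during optimization.
* The KDE utilization distribution underestimates the autocorrelation
  adjustment of track-aware estimators; areas are for descriptive
  comparison only.
* Stepwise AIC with 7-parameter covariate blocks can admit a spurious
  covariate when a candidate is incidentally correlated with a real driver;
  the independent forward/backward runs and their agreement flag are the
  guard rail.
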