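# Methods

## Model

A trial's cursor path `(x(t), y(t))` in normalized coordinates is
described by the gradient system

    τ ẋ = −∂V/∂x,    τ ẏ = −∂V/∂y,

a *descriptive* model of the motion, not a process model of the decision:
the attractors at the response locations simply encode that the trial ends
at one of them. The potential decomposes as
`V = V_x(x) + V_y(y) + V_xy(x, y)`:

- **Baseline** `V_x = x⁴/4 − x²/2`, `V_y = y³/3 − y²/2`, chosen so the
  one-dimensional derivatives factor as `x(x+1)(x−1)` and `y(y−1)`. The
  critical points are exactly `{−1, 0, 1} × {0, 1}`; the Hessian is
  diagonal with entries `(3x² − 1, 2y − 1)`, so (±1, 1) are attractors and
  (0, 0) a repellor. Integration constants are zero, hence `V(0,0) = 0`
  and `V(±1, 1) = −5/12`.
- **Coupling** `V_xy = Σ_{k=2..α} Σ_{i+j=k} c_ij x^i y^j / (k−1)`, for
  `i, j ≥ 1`. The per-degree divisor `(k−1)` normalizes term magnitudes
  across orders; with it the sole order-2 term is plain `c₁₁·x·y`, making
  `c₁₁` the elementary asymmetry parameter:
  `V(1,1) − V(−1,1) = 2·c₁₁` when only `c₁₁` is nonzero. Fitted
  coefficients are defined only up to this per-term scaling convention, so
  coefficients are comparable within this package but must be rescaled
  before comparison with implementations using a different convention.

Parameter vectors are ordered `τ` first, then `c_ij` by total degree
ascending and `i` descending — `[τ, c₁₁]` at α = 2, `[τ, c₁₁, c₂₁, c₁₂]`
at α = 3, seven entries at α = 4 — so fit results are comparable across
runs.

Note the baseline is unbounded below outside the arena (the cubic `V_y`
decreases without bound as y → −∞), which matters for simulation (below)
but not for fitting, which only evaluates the field at observed positions.

## Preprocessing

The chain mirrors standard mouse-tracking practice:

1. **Rescaling.** Device coordinates map affinely so the start position is
   (0, 0) and the targets (±1, 1): `x ← (x − start_x)/(right_x − start_x)`
   and `y ← (y − start_y)/(target_row_y − start_y)`; when the log uses
   screen pixels (y growing downward) the vertical denominator is negative
   and flips the axis. For layouts whose start is not centred between the
   targets the left target maps only approximately to −1.
2. **Trimming.** Leading samples within ε = 0.01 normalized units of the
   first sample are dropped except the last of them (movement-initiation
   dwell); trailing samples within ε of the final sample are dropped
   except the first of them (post-response dwell). The time origin resets
   to the first retained sample, so motion time is simply the trimmed
   duration. ε = 0.01 is 1% of the start-to-target half-width, below
   deliberate-motion scale. A path shorter than ε in total is rejected as
   degenerate.
3. **Resampling.** Linear interpolation onto a uniform grid of 101 points
   (configurable) spanning the trimmed duration; endpoints and duration
   are preserved exactly.
4. **Velocity estimation**, after resampling, on the uniform grid. Default
   is a Savitzky–Golay derivative filter with window 7 and polynomial
   order 2 (exact for polynomial motion up to the filter order, light
   smoothing otherwise); central finite differences with one-sided
   endpoints are the alternative. Both report velocities in normalized
   units per second.
5. **Canonicalization.** When a designated reference option (e.g. the
   high-reward one) sits on the left, x is negated and the choice flipped
   so the reference is always at x = +1.

The choice label is the sign of the final x; a final x of exactly 0 is
rejected as degenerate rather than guessed.

## Fitting

The per-trajectory error is the mean over samples of the squared
difference between model and data velocities (x- and y-components summed);
the multi-trajectory objective is the unweighted mean over trajectories.
Dividing by the number of samples actually summed (a true mean) and by N
leaves the argmin unchanged under any constant rescaling.

Because the model velocity is `−∇V/τ` with `V` polynomial, the objective's
partials with respect to τ and each `c_ij` are closed-form; they are
implemented analytically and verified against central finite differences
(1e−6 relative) in the tests. Optimization uses L-BFGS-B over
`(log τ, c_ij)` from the baseline start (τ = 0.05, all c = 0): the log
keeps τ positive while leaving the problem smooth, and `log τ` is capped
to [−8, 4] so degenerate fits (near-zero data velocities pushing τ to
infinity) stay finite and are reported via `converged=False` rather than
raising. Tolerance is a gradient norm of 1e−8 with a 500-iteration cap;
the returned objective never exceeds the baseline objective. Fitting is
deterministic for fixed inputs and options.

Under mirror reflection of the data (x and vx negated), the fitted
coefficients with odd `i` flip sign (c₁₁, c₁₂) while even-`i` ones (c₂₁)
and τ are unchanged — a useful end-to-end consistency check, exercised in
the test suite.

## Trajectory measures

- **Motion time**: duration of the trimmed trajectory.
- **Max-d**: the signed perpendicular deviation, at the sample of largest
  magnitude, from the chord through the trajectory's first and last
  points; positive when the deviating point lies toward the non-chosen
  option. The chord reference degrades gracefully when endpoints are
  imperfect; the idealized (0,0) → (choice, 1) diagonal is available via
  `reference="diagonal"`. Note the sign is choice-relative: fully
  mirroring a trajectory (x and choice both flipped) leaves signed max-d
  invariant.
- **Summaries**: per-option trial counts, mean motion time and mean max-d,
  plus the percentage choosing each option; options never chosen get N = 0
  and undefined means.

## Simulator

The forward generator integrates the gradient field with fixed-step
classical RK4 and stops on first entry into a 0.05-radius disc around
either target, or at t_max = 5 s. Defaults (dt = 1 ms, start offsets drawn
with scale 0.02 around the origin, zero noise) give baseline arrival times
of order 0.1–1 s at τ ≈ 0.05, the scale of real motion times. Optional
additive velocity noise (fresh Gaussian per step) is the minimal mechanism
for nonzero fitted residuals; the model itself is deterministic.
`symmetric_starts` mirrors each sampled offset so start-position asymmetry
cancels in expectation.

Because the potential is unbounded below past the arena edge, a
sufficiently tilted landscape can drive some starts across y ≈ 0 and off
to −∞ in finite time (the same tilt that flattens one attractor). The
integrator detects escape beyond radius 3 and reports it; the dataset
generator drops such trials, which is why a requested 20-trial set may
contain fewer trajectories. Real, preprocessed experimental data cannot
escape the arena, so this affects only synthetic generation.

What the synthetic data does not emulate: motor noise structure
(real hand movements have signal-dependent, temporally correlated noise),
submovement corrections, changes of mind (abrupt x-direction reversals),
reaction-time variability, and device quantization. Passing
parameter-recovery tests on this generator therefore shows the estimator
is consistent for trajectories that follow the model class, not that real
cursor data do.

## Problem sizes and numerical choices

Recovery studies in the tests and the acceptance script use 20 requested
trials of roughly 300–500 samples each before resampling to 101 points —
ample for a 4-parameter model while keeping a full pipeline run in
seconds. Recovery of (τ, c₁₁, c₂₁, c₁₂) from noise-free simulations is
within ~5% across seeds; the residual error stems from RK4/resampling
discretization and the Savitzky–Golay boundary treatment, not the
optimizer. Surface tabulation defaults to a 101×101 grid on
x ∈ [−1.2, 1.2], y ∈ [−0.2, 1.2].

## Known limitations

- Stationary, deterministic landscapes only; no change-of-mind or
  time-varying dynamics, and exactly two response options.
- Velocity matching trades accuracy for speed relative to fitting
  positions through the integrated system; with heavily smoothed or noisy
  velocity estimates the fitted landscape inherits that bias.
- No uncertainty quantification on fitted parameters; single-start local
  optimization (the baseline start has proved adequate on landscapes in
  the recommended α range, but multimodality at high α is untested).
- Interactive HTML output uses a deliberately small built-in wireframe
  renderer; it is for quick inspection, not publication graphics.
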