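# Methods

## The model

Quiet standing is modeled as a single-link inverted pendulum pivoting at
the ankle. With tilt angle θ (rad), body mass m, center-of-mass height h,
gravity g and rotational inertia I, the full model (ISDDE) is the
stochastic delay differential equation

    I θ̈(t) = mgh(1−K) θ(t) − B θ̇(t)
              − [ mgh P θ(t−τ) + D θ̇(t−τ) ]·Θ(t−τ)
              + σ_w w(t),            w(t) white standard Gaussian,

where the indicator Θ(t−τ) switches the delayed (active, neurally
mediated) feedback on only when the *lagged* phase point
(u, u̇) = (θ(t−τ), s·θ̇(t−τ)), with seconds constant s = 1 s, satisfies

    u (u̇ − α u) > 0   and   u² + u̇² > r².

K is the fraction of the gravitational toppling torque cancelled by
passive (instantaneous) stiffness, B passive damping (N·m·s/rad), P and D
the delayed proportional and derivative gains, τ the feedback delay (s),
r the insensitivity radius (rad) inside which no corrective action is
taken, and σ_w the white-noise intensity at the acceleration level
(Q = diag(0, σ_w²)). Observations are y_i = θ(t_i) + μ + ε_i with sway
origin μ and measurement-error variance ε. Two nested reductions are
provided: the SDDE (delayed terms always on) and the SDE (no delayed
terms).

**Switching-line parameterization.** The line slope is reparameterized
through the active fraction a as α = cot(aπ) = cos(aπ)/sin(aπ), so that
the active condition holds on exactly the fraction a of the phase plane
(outside the radius): the line makes angle π/2 − aπ with the position
axis. This mapping is monotone on (0, 1), makes a = 0.5 the regular
horizontal-line geometry, reduces the singular cases to the natural
endpoints a ∈ {0, 1} (never / always active, handled by clamping), and —
decisively — places the inactive wedge around the stable manifold of the
passive saddle, which is what the intermittent-control theory requires.
Under the alternative reading α = tan(aπ), a would not equal the active
fraction (a = 0 would mean 50 % active), a = 0.5 would be singular, and
every reference parameter set is dynamically unstable; we verified by
simulation that all six presets are stable under cot and divergent under
tan.

**Noise conventions.** σ_w is an acceleration-level intensity and the
simulator uses the identical convention, so parameter recovery is
internally consistent. ε is a variance: a sensor SD of 0.01 in
observation units corresponds to ε = 1e−4. Physical constants default to
m = 60 kg, h = 1 m, g = 9.81 m/s², I = mh² (the single-link point-mass
convention, under which mgh/I = g/h); recovery results do not depend on
this choice because simulator and filter share it. For real recordings,
h = 0.51 × standing height is the usual convention
(`ipcsway.io.com_height_from_stature`).

## Simulator

Euler–Maruyama at a fine step (default 1e−5 s) with the activation
re-evaluated every step from the buffered lagged state; the pre-history
before one delay interval holds the initial state constant, matching the
filter's backward extrapolation when its quadratic coefficient is zero.
Observation-rate series are obtained by plain decimation (no
anti-aliasing; the driving Wiener increments are self-similar), and
measurement noise is added afterwards. Divergence (|θ| > 1e8) raises an
error naming the blow-up time.

## Likelihood: delayed, switching Kalman filter

The −2 log-likelihood is the Gaussian prediction-error decomposition of a
continuous-discrete Kalman filter whose prediction step carries the
delayed input:

* exact zero-order-hold discretization per interval: Ad = exp(AΔt); the
  delayed input matrix is obtained inversion-free from the block
  exponential exp([[A, I], [0, 0]]Δt), so the singular K = 1 case is
  legal; Qd is the Van Loan integral (inside the hot loop all three are
  evaluated by scalar Taylor series at a halved step plus doubling
  identities — allocation-free, validated against `scipy.linalg.expm`);
* lagged states are linearly interpolated from the ring of *corrected*
  state means, λ = τ/Δt steps back (the mathematically standard
  interpolation sign; a verbatim compatibility mode for the printed
  alternative sign is available as `compat=True`, the two coincide at
  integer λ);
* for the first λ steps the lagged state comes from the quadratic
  backward extrapolation x0 + ẋ0(t−τ) + ẍ0(t−τ)², with ẍ0 a free fitted
  coefficient (no ½ factor);
* when consecutive lagged states straddle the activation boundary the
  prediction is split at the interpolated crossing (line intersection,
  first-order circle interpolation, or axis crossing by the quadrant
  rule; switching-on trades the roles of the two endpoints) with the
  interval divided in proportion to Euclidean distance along the segment;
* the delayed covariance is approximated by the current corrected
  covariance, and non-traversal active steps feed the interval-end lag —
  both exactly the conventions of the published algorithm; they are the
  source of the small, documented bias in B and D;
* the initial state covariance defaults to a diffuse 1e6·I. A degenerate
  P0 = 0 start couples the fitted initial values to the first observation
  through the (possibly tiny) measurement variance and creates a needle
  in the likelihood that no derivative-free optimizer can thread; with a
  diffuse start the first two observations lock position and velocity,
  the initial values act only through the lagged pre-history (their
  actual role), and only a few constant terms are added to −2lnL. P0 is
  an argument for users who want the deterministic convention.

Degenerate geometry (zero-length or line-parallel segments) falls back to
the segment midpoint; crossings nudged outside the segment by the circle
linearization are clamped to the nearest endpoint so the time split stays
a partition. A collapsed innovation variance or non-finite state returns
a large finite penalty (1e12) so global optimizers can keep ranking
candidates.

## Estimation

The likelihood is maximized by DE/rand/1/bin with per-vector dither
(each trial vector's scale factor uniform on [F, 1]), population 30,
crossover probability 0.95, F = 0.15, no success-weighting, stopping on a
500-generation no-improvement window at relative tolerance 1e−10 or the
iteration cap; bound violations re-draw the offending coordinate
uniformly. Structural parameters are shared across trials, nuisance
parameters (x0, ẋ0, ẍ0, μ) are appended per trial, and AIC = −2lnL + 2k
counts every estimated parameter (including both noise intensities).

A cold-started DE population reliably collapses onto a degenerate
solution that treats the series as a heavily smoothed random walk
(near-integrator dynamics, inflated process noise) before the switching
structure is found: partial structural improvements predict *worse* than
no structure, so the surface is deceptive and the basin of the true
parameters is extremely narrow relative to the bounds. The package
therefore wraps the DE core in three standard global-optimization
devices, all operating on the data alone:

1. **Gradient-matching warm start** (classical two-stage / collocation
   estimation): the series is smoothed and differentiated
   (Savitzky–Golay; window 5 samples for clean series, 51 for visibly
   noisy ones), and the acceleration is regressed on the instantaneous
   and lagged states under candidate switching geometries. For fixed
   (a, r, τ, μ) the gains are closed-form least squares; the four
   nonlinear parameters are scanned on a coarse grid (radius sweeps cost
   prefix sums because active sets are nested in r), the best cells per
   delay and per (active-fraction, radius) band are refined by
   Nelder–Mead on the regression RSS, and near-duplicates are merged.
   Candidates cluster into "families" by (a, r) geometry, each family
   holding its delay variants.
2. **Per-family DE runs**: each candidate family seeds one DE population
   (the geometry at several process-noise scalings, delay and radius
   variants, jittered clones), its lead member is pre-polished so the
   population starts with an incumbent already inside its basin, and one
   independently seeded DE runs per family (`restarts`, default 3;
   surplus restarts revisit the leading families with fresh seeds). The
   likelihood is easiest to enter from the soft-filter side, so the
   noise spread lets each family anneal from trajectory-matching toward
   the maximum-likelihood solution.
3. **Restarted Nelder–Mead polish**: the best member of each family (and
   finally the overall winner) descends the long, curved noise-intensity
   valley that a small population traverses slowly; restarts re-inflate
   the simplex until the gain per restart falls below 0.01. For joint
   multi-trial fits started from a known-good anchor, a cyclic
   block-coordinate variant (structural block, then each trial's
   nuisance block) converges substantially better per evaluation
   (`polish_mode="blocked"`).

For visibly noisy series the regression RSS is unreliable as a *ranking*
of switching geometries (errors-in-variables favour near-always-active
candidates), so `fit(init="grid")` replaces stage 1 by a likelihood-ranked
geometry grid: radii at data quantiles and a coarse active-fraction /
delay grid, gains refit per candidate, each candidate scored by the full
filter likelihood after a short local polish. The recovery studies use
this mode for their anchor fits.

All DE semantics inside each run follow the published settings; the
reported estimates are always the polished optimum of the full filter
likelihood, never the collocation values.

## Simulation studies

**Noiseless specification check.** Each preset is integrated
deterministically for 20 s at 1e−5 s from (x0, ẋ0) = (1, 0), decimated to
100 Hz and refit with 3000 DE iterations under the simulation bounds.
Structural estimates match the generating values to ~3–4 decimals except
B and D, which carry the expected discretization bias (≈ +0 to −10 % at
100 Hz), and the fitted noise intensities collapse toward zero.

**Noisy recovery.** Synthetic individuals contribute three 60 s trials at
100 Hz (process noise on, measurement noise at the preset ε, initial
state at the origin, sway origin 0) and are fitted jointly. Seeding fans
out from one master seed via `numpy.random.SeedSequence.spawn` (per
individual → per-trial process noise, per-trial measurement noise,
optimizer), so studies are bit-reproducible. The desk-scale default is 10
individuals per preset with a reduced optimizer budget; the first
individual receives the full likelihood-grid treatment and, once its fit
converges off the process-noise bound, anchors the starts of the
remaining individuals (all replicates share the generating parameters;
each reported estimate is still the polished optimum of its own
individual's likelihood). Studies of structurally identical parameter
sets may hand an existing anchor over (`anchor=`), which the fits adapt
to their own noise level. Full 100-replicate studies are the same call
with larger `n_individuals` and budgets.

At this scale the recovery reproduces the published behavior of the
estimator: K, P, a, r and the noise intensities are recovered with small
bias; σ̂ is biased slightly upward and τ̂ downward by ~20–40 ms; B̂ and D̂
are noisy and partially exchangeable with their delayed/instantaneous
counterparts — these are properties of the method on this model class,
not implementation artifacts, and they match the published recovery
tables qualitatively and quantitatively.

## What the synthetic generator does and does not emulate

The generator produces exactly the model's dynamics: stationary
intermittent sway, delay-induced oscillation, Gaussian process and
measurement noise. It does not emulate non-stationary drifts, trial
initiation/termination transients (real recordings should be trimmed;
see `preprocess`), sensor quantization, multi-segment kinematics, or
non-Gaussian disturbance bursts. Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own
assumptions, not robustness to misspecification — the latter is exactly
what the AIC comparison across ISDDE/SDDE/SDE variants probes on real
data.

## Numerical choices and limitations

* Discretization Taylor series: 13 terms after scaling to ‖AΔt‖ ≤ 0.25;
  agreement with `scipy.linalg.expm` paths to ~1e−12.
* Activation thresholds follow the printed strict/non-strict
  inequalities; boundary points are inactive.
* a is clamped to [1e−9, 1−1e−9] when building models so optimizer
  proposals at the singular endpoints behave as never/always active.
* The filter's covariance step uses scalar arithmetic with clamping of
  negative diagonal round-off; innovations with S ≤ 1e−300 penalize the
  candidate rather than raising.
* Delay interpolation clamps buffer lookups to the newest corrected
  state when τ < Δt.
* Likelihood values are comparable only within one data set and one P0
  convention (diffuse P0 adds data-independent constants).
* Standard errors are not computed (the likelihood is non-differentiable
  across switching events); model comparison uses AIC only.
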