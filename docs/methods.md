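# Methods

## Generative model

One trial of the penalty-shot game is a time series of screen positions
`y_t = (x_puck, y_puck, y_goalie)` in normalized coordinates ([-1, 1] in
both axes, x rightward, y upward), sampled at nominally 60 Hz
(`dt = 1/60 s`).  The shooter controls the puck in two dimensions, the
goalie the bar's vertical position; per-dimension maximum speeds `vmax`
(screen units per step) are part of the game configuration and, when
ingesting recorded data, are estimated as the sessionwide maximum
absolute per-step displacement.

The model stacks three layers:

1. **Physics.** `y[t+1] = clamp(y[t] + vmax ⊙ υ[t])` with joystick input
   `υ ∈ [-1, 1]³`.  A trial ends when the puck's leading edge reaches the
   goal line, when puck and bar overlap (bar interception takes
   precedence if both happen in one step), or after 10 s without shooter
   input (rolling clock, resetting on movement; a flag switches to a
   from-start clock).
2. **Control.** `υ = tanh(u)` links the joystick to an unbounded latent
   control signal.  Control increments follow a three-tap filter of the
   error history `e_t = g_t − y_t` against the latent goal, plus Gaussian
   noise of scale `ε` per dimension.  The taps derive from PID constants
   `(κ, Ti, Td)`; pure proportional control is `(1, −1, 0)` and makes
   `u_t = κ e_t` exactly (telescoping).  The filter is learned directly
   in tap space (three free coefficients per dimension): after the
   proportional warm start the taps are the identifiable object, and the
   PID parameterization remains available as a constructor.
3. **Goals.** Each player's goal performs a Markov walk whose conditional
   law interpolates between staying put (kinetic term, diffusion scale
   `σ`) and a state-dependent Gaussian-mixture potential
   `(w_k, μ_k, λ_k) = NN(s_t)` (softmax / softplus output maps).  The
   state `s_t` holds both players' positions and velocities plus
   per-session covariates (a session trend in [0, 1] and a binary
   condition flag).  Shooter (D = 2) and goalie (D = 1) have separate
   potentials over their own goal dimensions, both reading the full
   shared state.  The first goal of a trial is drawn from a learned
   K0-component diagonal GMM, and a five-step bootstrap defines the
   pre-movement error/control history.

The tanh Jacobian between `υ` and `u` is omitted from the likelihood: it
depends only on observed quantities, hence is constant in all latent
variables and all parameters except `ε`, whose exponential prior
dominates its scale.  Joystick inversion clips at `1 − δ` with
`δ = 1e−5`, bounding `atanh` at ≈ 6.1 — the same order as the hinge
margin on goal modes, so saturated steps cannot inject unbounded errors.

## Inference

The posterior over a trial's full goal path (all three goal dimensions
jointly, so cross-agent correlations are representable) is a structured
Gaussian: a mean network plus two networks producing the diagonal and
sub-diagonal 3×3 blocks of the lower block-bidiagonal Cholesky factor R
of the precision.  Sampling is reparameterized, `g = m + R^{-T} ζ`, with
exact `log q`.  The Monte-Carlo ELBO (one sample per step by default;
configurable) combines the control likelihood, initial-goal and
transition densities, and −log q, plus three penalties from the training
recipe: an exponential prior on `ε` (weight ρ = 1e5, applied at dataset
scale), an exponential prior on component variances (−γ/λ per component
and time point, γ = 0.1), and a hinge that linearly penalizes mixture
modes beyond 1.5× the game area (weight 100 per unit excess — the recipe
specifies linearity but not a slope; 100 is strong enough to keep modes
onscreen without distorting interior solutions).

Training uses ADAM (gradient ascent) in two phases: a warmup with taps
frozen at pure proportional, then a main phase with free taps, stopping
early when the exponential moving average (half-life 10 epochs) of the
per-epoch training ELBO changes by less than 1% for 5 consecutive epochs
(holdout ELBO is logged throughout; 15% of trials are held out).

### Design choices the original recipe leaves open

These were the decisive choices for making the optimization find the
control-consistent posterior rather than degenerate local optima
(posterior collapse onto flat goal paths with inflated `ε`, or taps
collapsing to zero):

* **Recognition input windows** span `lag` past and `lead` future samples
  (defaults 10 and 5) around each goal's paired observation.  The
  posterior is a smoother — the main evidence for a goal is the movement
  it subsequently causes — so future context is essential.  Windows carry
  both raw positions and the recovered control `u = atanh(υ)`: the
  per-step evidence lives on the control scale, which raw positions only
  encode through ~50× smaller adjacent differences.
* **Posterior-mean initialization and staging.**  The mean is the current
  position plus a linear skip term plus an MLP correction; the skip
  starts at the proportional-control inversion `g = y + atanh(υ)` (the
  exact goal estimate under the warm-start controller) and the whole mean
  is frozen during warmup, so the potential network first learns to
  explain these paths.  After warmup the mean moves at the taps' slower
  learning rate (1e−3): mean amplitude and control gain ride the same
  weakly identified direction (below).
* **Precision initialization** at the kinetic-prior structure: diagonal
  Cholesky entries at `sqrt(2)/σ`, sub-diagonal blocks at `−β/D` — the
  exact factor of the pure random-walk posterior.
* **Potential initialization** near the pure-diffusion limit
  (`λ ≈ 0.05`): an untrained potential then exerts almost no arbitrary
  pull on the posterior.
* The first-observation control prediction uses the bootstrap
  `u_0 = L0 e_0` deterministically; the generator adds noise to `u_0` as
  to every other step.  This one-term noise mismatch is negligible and
  keeps the graph simple.
* Desk-preset learning rate 5e−3 for network parameters (paper-scale
  config keeps 1e−3 everywhere); minibatches of 25 trials; stopping
  statistic on the training ELBO with holdout logged.

### Identifiability of the control gain

The control equations admit a near-symmetry: rescaling all errors
`e → e/c` while rescaling the proportional gain `κ → cκ` leaves the
control likelihood unchanged (the original description notes this
ambiguity and resolves it by the proportional warm start).  The symmetry
is broken only by the fixed diffusion scale σ through the posterior
entropy — a second-order effect.  In practice, on desk-scale synthetic
data the goalie's gain recovers to ~1% but shooter gains converge slowly
along this direction and can overshoot for strongly bimodal (feint)
dimensions; goal-path *shapes* are recovered essentially perfectly
(per-trial correlation ≈ 0.97) while their amplitude/gain trade-off
remains soft.  The acceptance suite reports both; the tap-recovery check
is the strictest and can fail on shooter dimensions at this scale.

## Synthetic data generator

The generator rolls the full generative stack (bootstrap → conditional
goal sampling → PID control + noise → tanh → physics → termination) with
closed-form scenario potentials, so recovery targets are unambiguous:

* `tracker` goalie: one component at an anticipatory aim
  `y_puck + 8·v_puck` with strong pull (λ = 2); `lagged_tracker` is the
  same aim with weak pull (λ = 0.05), a sluggish pursuer.
* `two_mode_feint` shooter: components at the screen edge's top and
  bottom (x at 1.0 — shooters aim past the goal line).  Weight logits
  combine a self-reinforcing commitment to the current heading with an
  opposing term proportional to the goalie's pursuit velocity whose gain
  ramps with puck–bar proximity (a product of saturating functions of
  different state variables, so the affine "linear" variant is genuinely
  misspecified — the premise of the model-comparison experiment).
* `straight_shot`: a single component whose vertical target amplifies the
  current heading (committed runs).
* `mixed`: straight mode plus the feint pair, with the feint weight
  increasing in the session-trend covariate — the injected
  across-session complexity drift that the change-point analyses must
  detect.

Default conditions: 500 trials across 10 sessions, control gains
κ = (1.2, 1.2, 0.8), control noise ε = 0.003 (the minimal-noise regime
the model asserts), goal diffusion σ = 0.015, goalie speed 0.012 and bar
half-height 0.12 (titrated, like the original task, toward roughly
balanced win rates).  σ = 0.015 is larger than the 1e−3
used at full experimental scale: the desk-scale stiffness β = σ⁻²
otherwise demands ~10⁵ gradient steps.  The model's default σ remains
1e−3; fits to the synthetic data set σ to the generating value.

What the generator does **not** emulate: measurement noise and dropped
frames, gaze dynamics (gaze columns pass through untouched if present),
cross-trial learning within a session, and idiosyncratic player styles.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions, not fit quality on any
particular animal's data.

## Analyses

A change point of one joystick dimension is a step where the smoothed
input changes sign, is nonzero on both sides, and jumps by ≥ 1e−6, with
five samples trimmed at each end; the shooter's per-trial count sums its
two dimensions (the per-player histograms need a scalar per player).
Predictive R² regresses the final (smoothed) puck vertical position on a
predictor at fixed offsets from trial start or end over all trials long
enough (≥ 10 per offset); multi-column predictors are fit jointly by
OLS, so the state+goal ≥ state ordering is an exact nesting property.
Sessionwise summaries delegate the formal tests (one-way ANOVA across
sessions, Wald tests on trend and win-rate regressions, Fisher exact
tests on consecutive outcomes with Bonferroni correction, Ljung-Box
autocorrelation) to scipy/statsmodels routines.

## Numerical choices and problem sizes

All arrays are float64.  Mixture log-densities use log-sum-exp; the
block-bidiagonal solve is a custom autodiff primitive with an exact
vector-Jacobian product (dense per-trial triangular solves; ~300×300 at
T ≈ 100).  Degenerate inputs are rejected with diagnostics (non-finite
states, non-PD Cholesky diagonals, zero-width normalization ranges); a
constant regressor in session summaries reports a zero slope rather than
an error; NaN objectives skip the step, and a fully diverged epoch
restores the last checkpoint.

The test suite and acceptance script run everything at desk scale:
recovery uses 150 trials of T ≈ 100–150 steps, K = 3 components, 32-unit
networks and 30 + 90 epochs over 3 seeds; the variant comparison uses
250–300 trials, K = 2, 16-unit networks and 12 + 48 epochs over 5 seeds
(chosen because at this data volume larger networks overfit the
potential and lose to the affine variant on holdout regardless of their
training fit).  The full suite completes on one CPU in roughly 12
minutes.  Full-scale settings (K = K0 = 20, 128/64-unit networks, 30 +
500 epochs) are config-reachable.

## Known limitations

* Control-gain recovery is weakly identified (see above); only goal-path
  shape recovery is robust at desk scale.
* Saturated joystick steps are clipped, not treated as censored
  observations.
* The recognition model is amortized per time step from finite windows;
  very long-range posterior dependencies are captured only through the
  precision's block-tridiagonal structure.
* The ELBO stopping rule watches the training ELBO; with very small
  datasets it can stop before the taps settle.
* With only hundreds of trials, the NN-GMM potential's holdout advantage
  over the affine variant is marginal and seed-dependent; the decisive
  advantage of flexible potentials emerges at data volumes (thousands of
  trials) beyond the desk-scale suite.
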