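# goaldyn

Latent-goal modelling of dynamic two-player interaction in the **penalty
shot** task: a "shooter" steers a puck (2-D) toward a goal line while a
"goalie" moves a vertical bar (1-D) to intercept it, both via joysticks
sampled at ~60 Hz.  `goaldyn` provides the game simulator, a generative
model of play built from interpretable parts, black-box variational
inference of each trial's latent goal trajectory, counterfactual trial
completion, and change-point analyses of strategic complexity — all
testable end-to-end on synthetic data with known ground truth.

It is aimed at researchers modelling continuous, real-time sensorimotor
decision data (behavioural neuroscience, motor control, multi-agent
behaviour) who want single-trial latent-intention estimates rather than
trial-averaged summaries.

## The model

Observed positions `y_t = (x_puck, y_puck, y_goalie)` evolve as

    y[t+1] = y[t] + vmax ⊙ tanh(u[t]),

where `u` is a latent control signal bounded to the joystick range by the
tanh link.  Control is driven by a per-player, per-dimension PID filter
with error `e_t = g_t − y_t` against a latent **goal** `g_t` — the
onscreen location the player currently steers toward:

    Δu_t = L0 e_t + L1 e_{t−1} + L2 e_{t−2} + N(0, ε²),
    L = κ·(1 + Δt/Ti + Td/Δt, −1 − 2Td/Δt, Td/Δt).

Goals follow a Markov process balancing a smoothness (kinetic) term
against a state-dependent potential whose exponential is a Gaussian
mixture with parameters produced by a neural network from the game state
`s_t` (positions, velocities, session covariates):

    k ~ Categorical(w(s_t)),
    g_t | g_{t−1}, k ~ N( (g_{t−1} + λ_k μ_k) / (1 + λ_k),  σ²/(1 + λ_k) ),

elementwise per goal dimension, with `softmax`/`softplus` output maps
ensuring `Σ w_k = 1` and `λ > 0`.  Inference maximizes a Monte-Carlo
evidence lower bound with a structured Gaussian recognition model over
whole goal paths (mean network + block-bidiagonal precision-Cholesky
networks), trained with ADAM in two phases: taps frozen at pure
proportional control (1, −1, 0) during warmup, free afterwards.  Simpler
variants (single Gaussian; affine parameter maps) are available for model
comparison, and fitted models complete observed trial prefixes — with
optionally clamped goals — for counterfactual experiments.

## Worked example

With a config file `cfg.yaml` selecting a 200-trial dataset and a small
fit (`fixture: {n_trials: 200, max_steps: 150}`, `train: {K: 3, sigma:
0.015, warmup_epochs: 30, main_epochs: 90, stop_tol: 0.0}`):

```bash
goaldyn --seed 7 --config cfg.yaml simulate --out data/
goaldyn --seed 7 --config cfg.yaml fit --data data/ --out model/
goaldyn --seed 7 recover --data data/ --model model/ --out recovery.json
```

`simulate` writes synthetic trials (trajectory + ground-truth goal CSVs)
from scripted agents — a two-mode "feint" shooter against a pursuit
goalie — with known control gains (1.2, 1.2, 0.8).  `fit` trains the
full model and logs per-epoch ELBOs; the run above prints

```
epoch 0 phase 1 ELBO -2471.19 holdout -169.59
epoch 30 phase 2 ELBO 486.30 holdout 710.74
epoch 60 phase 2 ELBO 664.98 holdout 806.12
epoch 119 phase 2 ELBO 769.90 holdout 829.72
```

(the per-trial training ELBO climbs steeply as the recognition model
concentrates and the fitted control noise shrinks toward its true
value).  `recover` compares the fit against the generator; the run above
reports

```json
{"l0_rel_error": [0.145, 0.101, 0.024], "mean_goal_correlation": 0.983}
```

— goal trajectories are recovered almost perfectly (per-trial
correlation 0.983), the goalie's control gain to within ~2%, while
shooter gains sit on the weakly identified gain direction discussed in
`docs/methods.md` (~10–15% here).

A library session covers the same ground programmatically:

```python
from goaldyn import FixtureConfig, generate_dataset, TrainConfig, fit
ds = generate_dataset(FixtureConfig(n_trials=200, seed=7))
model = fit(ds.trials, TrainConfig.desk(sigma=0.015, seed=7),
            game=ds.truth.game)
```

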