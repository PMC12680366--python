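# Methods

## The task

An agent must detect a hidden change. Each trial starts in an *unsafe* state
(s = 0) that switches to an absorbing *safe* state (s = 1) with probability
λ per time step. The agent sees one binary cue per step: in the safe state
every cue is *go* (x = 1); in every other phase a go occurs with probability
θ and a *nogo* (x = 0) with probability 1 − θ. The context θ — the rate of
misleading go cues — is constant within a block of trials and switches
between blocks, and is never cued explicitly. Acting in the safe state earns
+1 and ends the trial; acting earlier is premature. Because a nogo certifies
the unsafe state, the only behaviorally relevant statistic is the **waiting
time** τ: the number of consecutive go cues between the last nogo and the
action.

Two dialects share one integer-step engine (`flexinfer.task`):

* **network** (training timing): unsafe duration pre-drawn from an
  exponential with mean 10 steps (floor 1), a forced nogo on the first step
  of every trial, inter-trial intervals (ITIs) uniform on 5–25 steps with
  unsafe-like cue statistics, an optional −3 premature penalty during
  training (removed at evaluation), and a `max_trial_steps` guard that
  closes never-answered trials as `no_action`.
* **mouse** (experiment timing, 0.2 s bins): unsafe duration 4 + ⌊Exp(rate
  0.1)⌋ bins, safe state capped at 35 bins (`timeout` if the agent never
  acts), a 35-bin premature lockout after an early action, ITI uniform on
  5–25 bins. Waiting times convert to seconds at 0.2 s/bin.

**Block-switch timing.** The context switches "between trials", and the ITI
is exactly the stretch between trials: in this implementation the ITI that
separates two trials already carries the upcoming trial's θ. This matters
for inference-driven adaptation: the ITI shares unsafe-state cue statistics,
so an ideal observer harvests ten-odd steps of new-context evidence before
the first post-switch trial begins. With the alternative convention (ITI
keeps the old θ) a first trial after a switch toward high θ typically ends
before enough evidence arrives, and first-trial adaptation weakens to
second-trial adaptation.

Actions during the ITI are ignored (no reward, no phase change); the Markov
approximation below folds the ITI into the unsafe state, and penalizing ITI
actions would change the learning problem.

## The ideal observer (`flexinfer.bayes`)

The Markov approximation replaces blockwise context switches by a per-step
symmetric drift on an m-point grid {0, 1/m, …, (m−1)/m}: stay with
probability 1 − ε, otherwise jump uniformly to one of the other m − 1
values. State transitions are unsafe → safe with probability λ, safe
absorbing within a trial. The observer maintains the joint posterior
P(s, θ | x≤t) as a 2×m table, updated each step by propagating both kernels
and conditioning on the cue (renormalized every step to suppress
floating-point drift; a zero normalizer raises an inconsistent-belief
error). At each trial end the outcome reveals the previous state
(rewarded/timeout ⇒ safe, premature ⇒ unsafe); the next trial starts
certainly unsafe with the context marginal conditioned on that revealed
state. The filter also runs through ITI steps — they are informative about
θ under the Markov approximation.

**Waiting-time theory.** Write b = (1−λ)θ (misleading go), c = (1−λ)(1−θ)
(nogo), S(τ) = Σ_{k<τ} b^k. For the strategy "act after τ consecutive go
cues", the absorbing-chain success probability and expected trial duration
are

    R(τ; θ) = λ S / (1 − c S),
    T(τ; θ) = [τ b^τ + Σ_{k<τ} b^k (τλ + c(k+1))] / (1 − c S),

and the reward rate is r = R / (T + T_ITI). R is a probability, equals 1 at
θ = 0 (where T(1) = 1/λ), and both forms match Monte Carlo simulation of
the chain within sampling error (asserted in the test-suite at 10⁵ trials
per grid cell). A commonly quoted variant with numerator 1 − b^τ instead of
λS is retained as `reward_rate_curve_printed` for comparison; it exceeds 1
at θ = 0 and disagrees with the simulation, so nothing is built on it.

The policy: τ*(θ) = argmax_τ r(τ; θ) (smallest maximizer; the cap τ_max =
200 raises an explicit error if hit). Under context uncertainty the agent
maximizes the belief-averaged reward rate to get τ̂*, converts it into an
adaptive belief threshold ŝ* — the context-marginal average of the
known-context safe posterior after a nogo followed by τ̂* go cues — and acts
whenever the decision variable δ = ŝ − ŝ* is ≥ 0. With a point-mass context
belief this reproduces the fixed-τ*(θ) policy exactly, trial for trial
(the threshold is computed through the same filter code path, so the
equality is exact in floating point, not merely approximate).

**Defaults.** λ = 0.1, m = 20 (matching the 20-value training grid;
analyses with only {0.3, 0.7} contexts use m = 10, whose grid contains both
values), ε = 10⁻³, T_ITI = 15 (midpoint of the 5–25-step ITI). ε is the
agent's assumed volatility, not an environment parameter; the first-trial
adaptation result is insensitive to it over 10⁻³–3·10⁻² once the
block-switch timing above is in place.

## Heuristic integrators (`flexinfer.integrators`)

The disjoint drift-diffusion heuristic replaces the joint posterior by two
scalar recursions: a leaky context estimate θ̃ ← αθ̃ + (1−α)x and an
integrate-with-reset accumulator that climbs by 1/τ*(θ̃) per go (τ* looked
up on the model grid at the nearest grid point; linear interpolation
optional), resets on nogo, and acts at 1. θ̃ starts at the uninformative
midpoint 0.5 and keeps updating through ITIs (config flags for both
choices). Because safe-phase go cues enter the running average, θ̃
systematically overestimates θ. The performance sweep uses the 14-value
leak grid α ∈ {0.85, …, 0.995}.

The linear-output model (z ← αz + (1−α)x, Q = βz + ε₀, optionally one
baseline per context) is fitted under the constraints 0 < α < 1, β > 0,
ε₀ > 0 by a bounded 1-d search over α with a non-negative least-squares
inner solve; the fit uses the first 100,000 steps, the variance explained is
evaluated on the whole trace, and r² of a zero-variance target is defined as
0 with a warning.

## Recurrent agents (`flexinfer.rnn`)

Actor and critic are two separate single-layer LSTMs (100 units each at
full scale) with linear readouts, implemented in numpy with hand-derived
backpropagation through time (the backward pass is validated against
central finite differences in the test-suite). Inputs per step: cue,
previous action, previous reward, and (for the context variant) the current
θ. The actor readout yields two pre-activations whose difference Q_t sets
the act probability σ(Q_t) during training and a hard threshold Q_t > 0 at
evaluation. Weights initialize uniform(−1/√H, 1/√H); hidden states are zero
before the first episode and *carried across episodes* (values only,
gradients detached), so episode onsets are not signaled.

Training: 20-trial episodes at a per-episode θ drawn from 20 equally spaced
values in [0, 1] (a flag switches to the endpoint-free grid {0, …, 0.95});
returns G_t = R_t + γG_{t+1} with γ = 0.5, advantage A_t = γG_{t+1} + R_t −
V_t, actor loss Σ −ln π(a_t)·A_t + 0.05·π(a_t) ln π(a_t) (the entropy term
exactly as this recipe prescribes — only the chosen action enters), critic
loss 0.01·Σ A_t². The terminal return is bootstrapped as G_T = V at the
final step — the value at the first post-episode step is not observable
without consuming the next episode's stream — and the bootstrap is an
explicit argument of the pure loss function, so this choice is isolated.
RMSprop (lr 5·10⁻⁴ decaying ×0.99 every 10 episodes, smoothing 0.99,
momentum and weight decay 10⁻³) updates all parameters for the `trained`
variant and only the readouts for the two reservoir variants. Readout-only
agents keep softmax sampling at evaluation (a hard threshold leaves them
essentially non-functional); trained agents evaluate with the deterministic
threshold. Premature actions cost −3 during training, 0 at evaluation.

**Scales.** The full recipe is 10,000 episodes × 10 networks per variant
(hours of CPU). The first-class scaled-down profile used by the default
analysis scripts, the test-suite, and the acceptance script is 1,000
episodes with 50 units, which already separates the variants: the trained
network's reward rate approaches the Bayes agent's at θ = 0.3 and its mean
waiting time increases from θ = 0.3 to θ = 0.7, while the reservoir stays
far below with the opposite tendency.

## Analyses (`flexinfer.analysis`)

*Waiting times* come from responded trials only (rewarded or premature),
mirroring the lick-at-least-once inclusion rule; timeout/no-action trials
are dropped.

*Adaptation correlations*: for every block switch, the Pearson correlation
(across switch events, all sessions pooled) between single-trial waiting
times at positions −4…+4 around the switch and the previous/current block
means; block means exclude each block's first and last four trials, the
first four trials of each session are excluded, positions with fewer than
three events are reported missing, and blocks too short to trim are skipped
with a warning. The *crossover trial* is the earliest positive position
where the current-block correlation exceeds the previous-block one; a
planted adaptation lag L in the synthetic generator yields crossover L + 1
exactly.

*First-trial contrast*: per-subject mean first-trial waiting times in the
two contexts, compared by a two-sided paired Wilcoxon signed-rank test
(zeros dropped; all-tied cohorts return p = 1; fewer than five subjects is
an error). The implementation is checked against exhaustive enumeration of
sign assignments, and its type-I error calibrates to the nominal 5% under
null cohort simulations.

*PCA* runs on the actor's short-term-memory stream over all steps including
ITIs, mean-centered; PC signs are fixed by positive correlation with the
decision variable (PC1) and the context estimate (PC2) so projections are
reproducible.

*Decoding* uses trial steps only (ITI and lockout excluded): logistic
regression for the true state, linear regression for context variables, and
the Bayesian state estimate decoded in log-likelihood-ratio space
SLLR = ln(ŝ/(1−ŝ)) clipped at ±30 (ŝ is exactly 0 after every nogo). The
decision variable is decoded by regressing ŝ and ŝ* in SLLR space, mapping
back through the logistic, and differencing. Scores are held-out only:
10-fold by default, a random half split as the alternative scheme. Bayesian
target variables along a network's trajectory come from replaying the
filter on the recorded cue/outcome stream (`bayes_trace_along`).

*Vector fields*: a fixed 21-step cue sequence (one nogo, eight gos, twelve
nogos) is planted after a short closed-loop burn-in; the agent's actions
are masked (its action input forced to zero) so all agents see identical
data, and the mean per-step displacement of its internal coordinates is
recorded — (θ̂, ŝ) for the Bayes agent, (θ̃, s̃) for the integrator, PC
projections for networks. The diagnostic contrast: the trailing nogo
*raises* the Bayes context estimate (it certifies that the preceding gos
were misleading) while it *lowers* the leaky integrator's.

*Performance tables* report rewards per step including ITIs; when step
records are absent the ITI is charged at the configured mean.

## The synthetic-session generator (`flexinfer.synth`)

Emulates the statistical shape of rodent sessions so behavioral analyses
are testable with known ground truth: blocked schedules (no immediate
repeats, lengths uniform in 30–60 trials by default), per-trial waiting
times drawn from a discretized truncated normal (sd 1.5 by default) around
the target mean of the *effective* context, which lags the true block
context by L trials. L = 0 emulates an inference-driven (expert-like)
adapter, L ≥ 1 a feedback-driven learner; novice/expert contrasts are
emulated through the effect size and lag, not through a learning model. The
generator draws waiting times directly — it does not simulate cue streams,
lick kinematics, satiety, or within-session learning — so passing tests
certify the analysis pipeline's correctness and sensitivity, not any claim
about real mice.

## Numerical and design choices

- Belief tables renormalize every update; negativity/normalization asserted
  at 10⁻¹² in tests.
- argmax ties in τ break toward smaller τ (earlier action, identical rate).
- Unsafe durations are pre-drawn at trial start in both dialects; the mouse
  dialect uses 0.8 + 0.2⌊x⌋ s with x ~ Exp(rate 0.1), stored in 0.2 s bins.
- The known-context filter used for thresholds is the same code path as the
  trial filter, making the point-mass policy equivalence exact.
- θ = 1 is admitted in the environment (the default 20-value training grid
  includes it) although cues then carry no information in the unsafe state;
  reward-rate curves require θ < 1.
- The `no_action` outcome gives the Bayes agent no belief reset (no feedback
  was delivered); all other outcomes reveal the state.
- Problem sizes in the default scripts (4,000-trial comparisons, 3 session
  seeds, 1,000-episode training, 10⁵-trial Monte Carlo cells) were chosen so
  every analysis runs in minutes on one CPU while keeping sampling error an
  order of magnitude below the effects of interest; all are flags.

## Known limitations

- The full-scale network recipe (10 × 10,000 episodes per variant) is
  supported but not exercised by the default scripts; cohort-level
  statistics at that scale (PCA variance shares, decoding scores of ~0.9+)
  will differ quantitatively from the scaled-down profile's.
- The Markov-drift context model is an approximation to blockwise switches;
  ε is a modeling choice, and the belief filter is exact only for the
  drifting model, not the blocked generator.
- The linear-output fit assumes a single leak; outputs generated by
  mixtures of timescales are summarized, not identified.
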