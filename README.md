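# flexinfer

Flexible perceptual inference in a change-detection task: what should an
agent do when it must infer *what is happening* and *how reliable its
senses are* from the same stream of evidence?

Each trial starts in an *unsafe* state that switches to a *safe* state with
probability λ per time step. The agent sees one binary cue per step — in
the safe state every cue is *go*; elsewhere a go occurs with probability θ
(the latent context) and a *nogo* otherwise — and earns a reward only by
acting in the safe state. θ is constant within a block of trials and
switches unpredictably between blocks. Since a nogo certifies the unsafe
state, behavior reduces to the **waiting time** τ: how many consecutive go
cues to require before acting.

The package implements, end to end and with no external data:

- **`flexinfer.task`** — the discrete-time environment in two dialects
  (network-training timing and 0.2 s-bin experiment timing), block
  schedules, session logs and their CSV/JSON-lines round trip.
- **`flexinfer.bayes`** — the ideal observer: the joint belief
  𝒫ₜ(s, θ | x≤t) filtered over a discretized context grid,

      𝒫ₜ(s,θ) ∝ P(xₜ|s,θ) Σ_{s′,θ′} P(s|s′) P(θ|θ′) 𝒫ₜ₋₁(s′,θ′),

  the closed-form reward-rate theory — with b = (1−λ)θ, c = (1−λ)(1−θ),
  S = Σ_{k<τ} b^k:

      R(τ;θ) = λS/(1−cS),   r(τ;θ) = R/(T + T_ITI),   τ*(θ) = argmax_τ r,

  and the adaptive policy: act when the safe-state belief ŝₜ reaches the
  belief threshold ŝ* implied by the belief-averaged optimal waiting time
  (decision variable δ = ŝₜ − ŝ*).
- **`flexinfer.integrators`** — the heuristic alternative: a leaky context
  estimate θ̃ₜ = αθ̃ₜ₋₁ + (1−α)xₜ feeding an integrate-with-reset state
  accumulator, plus the constrained linear-output model used to test
  whether an agent's output is explainable by plain leaky integration.
- **`flexinfer.rnn`** — advantage actor-critic LSTM agents (trained,
  readout-only reservoir, reservoir + explicit context input) implemented
  in numpy with hand-derived backpropagation through time, following the
  printed recipe (γ = 0.5, entropy bonus 0.05, critic scale 0.01, RMSprop,
  hidden state carried across 20-trial episodes).
- **`flexinfer.analysis`** — waiting-time statistics, block-switch
  adaptation correlations (the *first-trial adaptation* signature of
  inference- vs feedback-driven behavior), paired Wilcoxon contrasts,
  hidden-state PCA, cross-validated decoding of Bayesian variables from
  network activity, and planted-stimulus vector fields.
- **`flexinfer.synth`** — a synthetic session generator with a planted
  adaptation lag and noise model, so every behavioral analysis can be
  validated against known ground truth.

The numbered scripts under `analysis/` are thin drivers over the library
(01 policy theory, 02 Bayes-agent behavior, 03 integrator comparison,
04 network training, 05 network analysis, 06 synthetic behavior); each
prints what it found and writes tables under `results/`.

## Worked example

```
python analysis/01_optimal_policy.py
```

prints the waiting-time theory table:

```
 theta  tau_star  reward_rate_at_optimum  belief_threshold
   0.0         1                0.040000          1.000000
   0.1         3                0.037033          0.993405
   0.3         4                0.035415          0.962462
   0.5         5                0.033527          0.906291
   0.7         7                0.031387          0.868268
```

Read: with perfectly reliable cues (θ = 0) the first go already proves the
transition (τ* = 1); as cues become less reliable the optimal policy waits
for longer go runs (τ* = 7 at θ = 0.7) while the belief level it demands
*falls* (0.87 vs 1.0) — in noisier contexts the agent must act on less
certainty or waste time. `python analysis/02_bayes_agent_behavior.py` then
runs the ideal observer in closed loop on blocked θ ∈ {0.3, 0.7} sessions:

```
  theta=0.3: reward rate 0.0342, mean tau 3.99, var 0.11 (1420 trials)
  theta=0.7: reward rate 0.0305, mean tau 6.91, var 0.28 (1380 trials)

Adaptation crossover at trial 1 after the switch (61 events):
  position -1: r_prev=+0.986  r_curr=-0.980
  position +1: r_prev=-0.354  r_curr=+0.369
  position +2: r_prev=-0.755  r_curr=+0.757
```

The agent's waiting times sit at the per-context optima (τ* = 4 and 7), and
on the *very first trial* after an uncued block switch they already
correlate more with the new block's mean than the old one's — adaptation by
inference, before any reward feedback could inform it.

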