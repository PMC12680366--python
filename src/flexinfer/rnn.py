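"""Actor-critic recurrent agents trained by policy gradient.

Two independent single-layer LSTM networks (actor and critic, 100 units
each by default) receive the cue x_t, the previous action and the previous
reward (plus, optionally, the explicit context theta). The actor's linear
readout produces two pre-activations Q(action) and Q(inaction); their
difference Q_t parametrizes the act probability sigmoid(Q_t) during training
and a hard threshold Q_t > 0 at evaluation. The critic reads out a scalar
value V_t used only to form the advantage

    A_t = gamma * G_{t+1} + R_t - V_t,    G_t = R_t + gamma * G_{t+1},

with the terminal return bootstrapped from the critic. Losses:

    loss_actor  = sum_t [ -ln pi(a_t) * A_t + 0.05 * pi(a_t) ln pi(a_t) ]
    loss_critic = 0.01 * sum_t (gamma * G_{t+1} + R_t - V_t)^2

optimized by RMSprop (lr 5e-4 decaying x0.99 every 10 episodes, momentum and
weight decay 1e-3) with full backpropagation through time per episode;
hidden states carry across episodes (values only, gradients detached).

Everything is implemented in numpy with hand-derived gradients; training is
fully deterministic given the seed. Variants: ``trained`` (all weights
learned), ``readout_only`` (random frozen recurrent/input weights, only the
readouts learned -- a reservoir), and ``readout_only_context`` (reservoir
plus an explicit context input channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .task import ChangeDetectionEnv, SessionLog, TaskConfig

__all__ = [
    "NetConfig",
    "RLHyperparams",
    "LSTMCell",
    "ActorCriticNet",
    "a2c_losses",
    "init_network",
    "train",
    "train_cohort",
    "evaluate",
    "NetworkAgent",
]

VARIANTS = ("trained", "readout_only", "readout_only_context")


@dataclass
class NetConfig:
    n_hidden: int = 100
    variant: str = "trained"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def n_inputs(self) -> int:
        # x, previous action, previous reward (+ explicit context)
        return 4 if self.variant == "readout_only_context" else 3

    @property
    def readout_only(self) -> bool:
        return self.variant in ("readout_only", "readout_only_context")


@dataclass
class RLHyperparams:
    gamma: float = 0.5
    entropy_coef: float = 0.05
    critic_scale: float = 0.01
    n_episodes: int = 10_000
    trials_per_episode: int = 20
    n_theta_train: int = 20
    theta_grid_includes_one: bool = True
    lr: float = 5e-4
    lr_decay: float = 0.99
    lr_decay_every: int = 10
    rms_alpha: float = 0.99
    momentum: float = 1e-3
    weight_decay: float = 1e-3
    train_penalty: float = -3.0

    @property
    def theta_train_grid(self) -> np.ndarray:
        if self.theta_grid_includes_one:
            return np.linspace(0.0, 1.0, self.n_theta_train)
        return np.arange(self.n_theta_train) / self.n_theta_train


# -- LSTM cell with hand-derived gradients -----------------------------------


class LSTMCell:
    """Single-layer LSTM; gate order i, f, g, o in one stacked weight matrix."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator) -> None:
        self.n_in = n_in
        self.n_hidden = n_hidden
        k = 1.0 / np.sqrt(n_hidden)  # uniform fan-in initialization
        self.W = rng.uniform(-k, k, size=(4 * n_hidden, n_in + n_hidden))
        self.b = rng.uniform(-k, k, size=4 * n_hidden)

    def forward(self, x: np.ndarray, h: np.ndarray, c: np.ndarray):
        H = self.n_hidden
        v = np.concatenate([x, h])
        z = self.W @ v + self.b
        i = _sigmoid(z[:H])
        f = _sigmoid(z[H : 2 * H])
        g = np.tanh(z[2 * H : 3 * H])
        o = _sigmoid(z[3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache = (v, i, f, g, o, c, tc)
        return h_new, c_new, cache

    def backward(self, dh: np.ndarray, dc: np.ndarray, cache, grads):
        """Accumulate parameter gradients; returns (dh_prev, dc_prev)."""
        v, i, f, g, o, c_prev, tc = cache
        H = self.n_hidden
        do = dh * tc
        dcc = dc + dh * o * (1.0 - tc * tc)
        di = dcc * g
        df = dcc * c_prev
        dg = dcc * i
        dc_prev = dcc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ]
        )
        grads["W"] += np.outer(dz, v)
        grads["b"] += dz
        dv = self.W.T @ dz
        return dv[self.n_in :], dc_prev


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        k = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-k, k, size=(n_out, n_in))
        self.b = rng.uniform(-k, k, size=n_out)


class ActorCriticNet:
    """Separate actor and critic LSTMs with linear readouts."""

    def __init__(self, config: NetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        H, I = config.n_hidden, config.n_inputs
        self.actor = LSTMCell(I, H, rng)
        self.actor_out = _Linear(H, 2, rng)
        self.critic = LSTMCell(I, H, rng)
        self.critic_out = _Linear(H, 1, rng)
        self.reset_hidden()

    def reset_hidden(self) -> None:
        H = self.config.n_hidden
        self.ha = np.zeros(H)
        self.ca = np.zeros(H)
        self.hc = np.zeros(H)
        self.cc = np.zeros(H)

    def parameters(self) -> dict[str, np.ndarray]:
        p = {
            "actor.W": self.actor.W,
            "actor.b": self.actor.b,
            "actor_out.W": self.actor_out.W,
            "actor_out.b": self.actor_out.b,
            "critic.W": self.critic.W,
            "critic.b": self.critic.b,
            "critic_out.W": self.critic_out.W,
            "critic_out.b": self.critic_out.b,
        }
        return p

    def trainable_names(self) -> list[str]:
        if self.config.readout_only:
            return ["actor_out.W", "actor_out.b", "critic_out.W", "critic_out.b"]
        return list(self.parameters().keys())

    def forward_step(self, u: np.ndarray):
        """One step of both subnetworks; returns (Q, V, caches)."""
        ha, ca, cache_a = self.actor.forward(u, self.ha, self.ca)
        hc, cc, cache_c = self.critic.forward(u, self.hc, self.cc)
        self.ha, self.ca, self.hc, self.cc = ha, ca, hc, cc
        qa = self.actor_out.W @ ha + self.actor_out.b
        Q = float(qa[0] - qa[1])
        V = float((self.critic_out.W @ hc + self.critic_out.b)[0])
        return Q, V, (cache_a, cache_c, ha, hc)

    def save(self, path) -> None:
        arrs = {k.replace(".", "__"): v for k, v in self.parameters().items()}
        np.savez(
            path,
            __variant=self.config.variant,
            __n_hidden=self.config.n_hidden,
            __seed=self.config.seed,
            **arrs,
        )

    @classmethod
    def load(cls, path) -> "ActorCriticNet":
        data = np.load(path, allow_pickle=False)
        cfg = NetConfig(
            n_hidden=int(data["__n_hidden"]),
            variant=str(data["__variant"]),
            seed=int(data["__seed"]),
        )
        net = cls(cfg)
        for k, v in net.parameters().items():
            v[...] = data[k.replace(".", "__")]
        return net


def init_network(config: NetConfig) -> ActorCriticNet:
    return ActorCriticNet(config)


# -- losses ------------------------------------------------------------------


def a2c_losses(
    rewards: np.ndarray,
    values: np.ndarray,
    q_values: np.ndarray,
    actions: np.ndarray,
    gamma: float,
    v_bootstrap: float,
    entropy_coef: float = 0.05,
    critic_scale: float = 0.01,
):
    """Actor and critic losses of one episode, plus returns and advantages.

    ``v_bootstrap`` is the terminal return G_T. Pure function of its inputs
    so the arithmetic can be checked against hand computation.
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    q_values = np.asarray(q_values, dtype=float)
    actions = np.asarray(actions, dtype=int)
    T = len(rewards)
    G = np.empty(T + 1)
    G[T] = v_bootstrap
    for t in range(T - 1, -1, -1):
        G[t] = rewards[t] + gamma * G[t + 1]
    adv = gamma * G[1:] + rewards - values
    p_act = _sigmoid(q_values)
    pi = np.where(actions == 1, p_act, 1.0 - p_act)
    pi = np.clip(pi, 1e-12, 1.0)
    actor_loss = float(np.sum(-np.log(pi) * adv + entropy_coef * pi * np.log(pi)))
    critic_loss = float(critic_scale * np.sum(adv**2))
    return actor_loss, critic_loss, G, adv


def _dloss_dQ(
    q_values: np.ndarray, actions: np.ndarray, adv: np.ndarray, entropy_coef: float
) -> np.ndarray:
    """Analytic gradient of the actor loss w.r.t. Q_t (advantage detached)."""
    p = _sigmoid(q_values)
    pi = np.where(actions == 1, p, 1.0 - p)
    pi = np.clip(pi, 1e-12, 1.0)
    dpi_dQ = np.where(actions == 1, p * (1.0 - p), -p * (1.0 - p))
    pg = -(adv / pi) * dpi_dQ
    ent = entropy_coef * (np.log(pi) + 1.0) * dpi_dQ
    return pg + ent


# -- optimizer ---------------------------------------------------------------


class _RMSprop:
    def __init__(self, params: dict, hp: RLHyperparams) -> None:
        self.hp = hp
        self.sq = {k: np.zeros_like(v) for k, v in params.items()}
        self.buf = {k: np.zeros_like(v) for k, v in params.items()}
        self.lr = hp.lr
        self.eps = 1e-8

    def step(self, params: dict, grads: dict, names: list[str]) -> None:
        hp = self.hp
        for k in names:
            g = grads[k] + hp.weight_decay * params[k]
            self.sq[k] = hp.rms_alpha * self.sq[k] + (1.0 - hp.rms_alpha) * g * g
            avg = np.sqrt(self.sq[k]) + self.eps
            self.buf[k] = hp.momentum * self.buf[k] + g / avg
            params[k] -= self.lr * self.buf[k]

    def decay(self) -> None:
        self.lr *= self.hp.lr_decay


# -- training ----------------------------------------------------------------


def _episode_env(
    task_config: TaskConfig, theta: float, trials: int, rng: np.random.Generator,
    training: bool,
) -> ChangeDetectionEnv:
    cfg = replace(
        task_config,
        theta_set=(float(theta),),
        block_length_range=(trials, trials),
        training=training,
    )
    return ChangeDetectionEnv(cfg, trials, rng=rng, record_steps=False)


def _run_episode(
    net: ActorCriticNet,
    env: ChangeDetectionEnv,
    rng: np.random.Generator,
    sample: bool,
    theta_input: float | None,
):
    """Roll one episode; returns per-step arrays and caches for BPTT."""
    rewards, values, qs, actions, caches, inputs = [], [], [], [], [], []
    prev_a, prev_r = 0.0, 0.0
    while not env.done:
        x = env.observe()
        u = [float(x), prev_a, prev_r]
        if theta_input is not None:
            u.append(theta_input)
        u = np.asarray(u)
        Q, V, cache = net.forward_step(u)
        if sample:
            p = _sigmoid(np.array([Q]))[0]
            a = int(rng.random() < p)
        else:
            a = int(Q > 0.0)
        r, _ = env.act(a)
        rewards.append(r)
        values.append(V)
        qs.append(Q)
        actions.append(a)
        caches.append(cache)
        inputs.append(u)
        prev_a, prev_r = float(a), float(r)
    return (
        np.array(rewards),
        np.array(values),
        np.array(qs),
        np.array(actions),
        caches,
        inputs,
    )


def _bptt(net: ActorCriticNet, caches, inputs, dQ: np.ndarray, dV: np.ndarray):
    """Backward pass through the episode; returns gradients by parameter name."""
    H = net.config.n_hidden
    grads = {k: np.zeros_like(v) for k, v in net.parameters().items()}
    ga = {"W": grads["actor.W"], "b": grads["actor.b"]}
    gc = {"W": grads["critic.W"], "b": grads["critic.b"]}
    readout_only = net.config.readout_only
    dha = np.zeros(H)
    dca = np.zeros(H)
    dhc = np.zeros(H)
    dcc = np.zeros(H)
    Wa = net.actor_out.W
    Wc = net.critic_out.W
    for t in range(len(caches) - 1, -1, -1):
        cache_a, cache_c, ha, hc = caches[t]
        # actor readout: Q = (W[0]-W[1]) @ h + (b[0]-b[1])
        grads["actor_out.W"][0] += dQ[t] * ha
        grads["actor_out.W"][1] -= dQ[t] * ha
        grads["actor_out.b"][0] += dQ[t]
        grads["actor_out.b"][1] -= dQ[t]
        grads["critic_out.W"][0] += dV[t] * hc
        grads["critic_out.b"][0] += dV[t]
        if readout_only:
            continue
        dha_t = dha + dQ[t] * (Wa[0] - Wa[1])
        dhc_t = dhc + dV[t] * Wc[0]
        dha, dca = net.actor.backward(dha_t, dca, cache_a, ga)
        dhc, dcc = net.critic.backward(dhc_t, dcc, cache_c, gc)
    return grads


def train(
    net_config: NetConfig,
    hyper: RLHyperparams,
    task_config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
    net: ActorCriticNet | None = None,
):
    """Train one network; returns (network, learning_curve) where the curve
    logs per-episode total reward and reward rate."""
    if task_config is None:
        task_config = TaskConfig(training=True)
    if rng is None:
        rng = np.random.default_rng(net_config.seed + 1)
    if net is None:
        net = init_network(net_config)
    hp = hyper
    params = net.parameters()
    frozen = {
        k: v.copy() for k, v in params.items() if k not in net.trainable_names()
    }
    opt = _RMSprop(params, hp)
    grid = hp.theta_train_grid
    curve = {"episode": [], "total_reward": [], "reward_rate": [], "actor_loss": [],
             "critic_loss": []}
    needs_theta = net_config.variant == "readout_only_context"
    for ep in range(hp.n_episodes):
        theta = float(grid[rng.integers(len(grid))])
        env = _episode_env(task_config, theta, hp.trials_per_episode, rng, True)
        rewards, values, qs, actions, caches, inputs = _run_episode(
            net, env, rng, sample=True, theta_input=theta if needs_theta else None
        )
        v_boot = values[-1] if len(values) else 0.0
        la, lc, G, adv = a2c_losses(
            rewards, values, qs, actions, hp.gamma, v_boot,
            hp.entropy_coef, hp.critic_scale,
        )
        if not (np.isfinite(la) and np.isfinite(lc)):
            raise FloatingPointError(
                f"non-finite loss at episode {ep}: actor={la}, critic={lc}"
            )
        dQ = _dloss_dQ(qs, actions, adv, hp.entropy_coef)
        dV = -2.0 * hp.critic_scale * adv
        grads = _bptt(net, caches, inputs, dQ, dV)
        opt.step(params, grads, net.trainable_names())
        if (ep + 1) % hp.lr_decay_every == 0:
            opt.decay()
        curve["episode"].append(ep)
        curve["total_reward"].append(float(rewards.sum()))
        curve["reward_rate"].append(float(rewards.sum() / max(len(rewards), 1)))
        curve["actor_loss"].append(la)
        curve["critic_loss"].append(lc)
    for k, v in frozen.items():
        if not np.array_equal(params[k], v):  # pragma: no cover - safety net
            raise AssertionError(f"frozen parameter {k} changed during training")
    return net, curve


def train_cohort(
    n_networks: int,
    net_config: NetConfig,
    hyper: RLHyperparams,
    task_config: TaskConfig | None = None,
):
    """Train ``n_networks`` with distinct seeds derived from the base seed."""
    nets, curves = [], []
    for i in range(n_networks):
        cfg = replace(net_config, seed=net_config.seed + 1000 * i)
        net, curve = train(cfg, hyper, task_config)
        nets.append(net)
        curves.append(curve)
    return nets, curves


# -- evaluation --------------------------------------------------------------


class NetworkAgent:
    """Adapter exposing the session-runner agent protocol for a network."""

    def __init__(
        self, net: ActorCriticNet, mode: str = "argmax",
        rng: np.random.Generator | None = None, theta_input: float | None = None,
        record: bool = False,
    ) -> None:
        if mode not in ("argmax", "softmax"):
            raise ValueError("mode must be 'argmax' or 'softmax'")
        self.net = net
        self.mode = mode
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.theta_input = theta_input
        self.record = record
        self.trace: dict[str, list] = {"h": [], "Q": [], "V": [], "action": []}
        self._prev_a = 0.0

    def step(self, x: int, prev_reward: float) -> int:
        u = [float(x), self._prev_a, float(prev_reward)]
        if self.theta_input is not None:
            u.append(self.theta_input)
        Q, V, cache = self.net.forward_step(np.asarray(u))
        if self.mode == "argmax":
            a = int(Q > 0.0)
        else:
            p = _sigmoid(np.array([Q]))[0]
            a = int(self.rng.random() < p)
        if self.record:
            self.trace["h"].append(cache[2].copy())  # actor short-term memory
            self.trace["Q"].append(Q)
            self.trace["V"].append(V)
            self.trace["action"].append(a)
        self._prev_a = float(a)
        return a

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v) for k, v in self.trace.items()}


def evaluate(
    net: ActorCriticNet,
    task_config: TaskConfig,
    n_trials: int,
    mode: str = "argmax",
    rng: np.random.Generator | None = None,
    theta_input_from_env: bool = False,
    record_trace: bool = True,
):
    """Frozen-weight evaluation (no premature penalty); returns the session
    log and the per-step trace (actor hidden states, Q, V, action, plus
    environment annotations)."""
    cfg = replace(task_config, training=False)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    env = ChangeDetectionEnv(cfg, n_trials, rng=rng, record_steps=record_trace)
    needs_theta = net.config.variant == "readout_only_context" or theta_input_from_env
    agent = NetworkAgent(
        net, mode=mode, rng=rng,
        theta_input=0.0 if needs_theta else None, record=record_trace,
    )
    prev_r = 0.0
    while not env.done:
        if needs_theta:
            agent.theta_input = float(env.state.theta_current)
        x = env.observe()
        a = agent.step(x, prev_r)
        prev_r, _ = env.act(a)
    log = SessionLog(trials=list(env.trials), block_schedule=list(env.schedule),
                     config=cfg)
    trace = agent.arrays() if record_trace else {}
    if record_trace:
        ann = {"x": [], "s_true": [], "theta_true": [], "phase": [], "consec_go": [],
               "r": [], "trial_index": []}
        for t in log.trials:
            for rec in t.steps:
                ann["x"].append(rec.x)
                ann["s_true"].append(rec.s_true)
                ann["theta_true"].append(rec.theta_true)
                ann["phase"].append(rec.phase)
                ann["consec_go"].append(rec.consec_go)
                ann["r"].append(rec.r)
                ann["trial_index"].append(t.trial_index)
        for k, v in ann.items():
            trace[k] = np.asarray(v)
    return log, trace
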