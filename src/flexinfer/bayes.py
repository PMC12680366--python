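"""Bayes-optimal joint inference of latent state and context.

The ideal observer maintains a joint posterior (belief state) over the binary
safety state s and a discretized context grid theta, updated each step by
propagating through the state/context transition kernels and conditioning on
the binary cue (Chapman-Kolmogorov + Bayes). The policy is a waiting-time
construction: for each context the reward rate r(tau; theta) of the
"act after tau consecutive go cues" strategy has a unique finite maximizer
tau*(theta); under context uncertainty the agent maximizes the belief-averaged
reward rate, converts the resulting waiting time into an adaptive belief
threshold s*, and acts whenever the current safe-state belief reaches it.

Closed forms. With b = (1-lambda)*theta (misleading go), c = (1-lambda)*(1-theta)
(nogo) and S = sum_{k<tau} b^k, the success probability of the absorbing
go-run chain is

    R(tau; theta) = lambda * S / (1 - c * S),

the expected trial duration is

    T(tau; theta) = [tau b^tau + sum_{k<tau} b^k (tau lambda + c (k+1))] / (1 - c S),

and the reward rate is r = R / (T + T_iti). R equals 1 at theta = 0 and is a
probability for all parameters; both forms are cross-checked against Monte
Carlo simulation of the chain in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import ChangeDetectionEnv, SessionLog, TaskConfig

__all__ = [
    "BayesModel",
    "BeliefState",
    "Estimates",
    "RewardRateCurve",
    "PolicyDecision",
    "InconsistentBeliefError",
    "context_transition_matrix",
    "state_transition_matrix",
    "emission_likelihood",
    "belief_update",
    "estimates",
    "reset_after_feedback",
    "reward_rate_curve",
    "reward_rate_curve_printed",
    "optimal_tau",
    "expected_optimal_tau",
    "belief_threshold",
    "safe_posterior_after_run",
    "decide",
    "BayesAgent",
    "run_bayes_agent",
    "simulate_chain",
]

_NORM_TOL = 1e-12


class InconsistentBeliefError(RuntimeError):
    """Observation has zero likelihood under the current belief."""


@dataclass
class BayesModel:
    """Known world model of the ideal observer.

    lambda_ : unsafe -> safe transition probability per step
    epsilon : per-step context drift probability
    m       : context grid size; grid is {0, 1/m, ..., (m-1)/m} unless a
              custom ``theta_grid`` is supplied (e.g. a known-context point)
    T_iti   : average inter-trial interval in steps (reward-rate time cost)
    tau_max : search cap for waiting-time optimization
    """

    lambda_: float = 0.1
    epsilon: float = 1e-3
    m: int = 20
    T_iti: float = 15.0
    tau_max: int = 200
    theta_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_ <= 1.0):
            raise ValueError("lambda_ must be in (0, 1]")
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if self.theta_grid is None:
            self.theta_grid = np.arange(self.m) / self.m
        else:
            self.theta_grid = np.asarray(self.theta_grid, dtype=float)
            self.m = len(self.theta_grid)
        if self.m == 1 and self.epsilon > 0:
            raise ValueError("epsilon must be 0 when m == 1")

    # transition kernels are fixed; cache them
    @property
    def P_theta(self) -> np.ndarray:
        return context_transition_matrix(self.m, self.epsilon)

    @property
    def P_s(self) -> np.ndarray:
        return state_transition_matrix(self.lambda_)


@dataclass
class BeliefState:
    """Joint posterior table p[s, j] = P(s, theta_j | observations)."""

    p: np.ndarray  # shape (2, m)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != 2:
            raise ValueError("belief table must have shape (2, m)")

    def check(self) -> None:
        if np.any(self.p < -_NORM_TOL):
            raise ValueError("belief has negative entries")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("belief not normalized")

    @property
    def context_marginal(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @classmethod
    def uniform(cls, m: int) -> "BeliefState":
        return cls(np.full((2, m), 1.0 / (2 * m)))

    @classmethod
    def initial(cls, model: BayesModel) -> "BeliefState":
        """Trial-start belief: certainly unsafe, uniform over contexts."""
        p = np.zeros((2, model.m))
        p[0] = 1.0 / model.m
        return cls(p)


@dataclass
class Estimates:
    s_hat: float
    theta_hat: float


@dataclass
class RewardRateCurve:
    theta: float
    b: float
    c: float
    tau: np.ndarray
    R: np.ndarray
    T: np.ndarray
    r: np.ndarray


@dataclass
class PolicyDecision:
    tau_star_expected: int
    s_threshold: float
    delta: float
    act: bool


# -- kernels and likelihood --------------------------------------------------


def context_transition_matrix(m: int, epsilon: float) -> np.ndarray:
    """P(theta | theta') = (1-eps) I + eps/(m-1) (1 - I); rows sum to 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must be in [0, 1)")
    if m == 1:
        if epsilon > 0:
            raise ValueError("epsilon must be 0 when m == 1")
        return np.ones((1, 1))
    P = np.full((m, m), epsilon / (m - 1))
    np.fill_diagonal(P, 1.0 - epsilon)
    return P


def state_transition_matrix(lambda_: float) -> np.ndarray:
    """Column-stochastic P[s, s']: unsafe -> safe w.p. lambda, safe absorbing."""
    if not (0.0 < lambda_ <= 1.0):
        raise ValueError("lambda_ must be in (0, 1]")
    return np.array([[1.0 - lambda_, 0.0], [lambda_, 1.0]])


def emission_likelihood(x: int, s: int, theta) -> float:
    """P(x | s, theta): safe always emits go; unsafe emits go w.p. theta."""
    if s == 1:
        return 1.0 if x == 1 else 0.0
    return theta if x == 1 else 1.0 - theta


# -- belief filtering --------------------------------------------------------


def belief_update(belief: BeliefState, x: int, model: BayesModel) -> BeliefState:
    """One filtering step: propagate state and context kernels, condition on
    the cue, renormalize."""
    p = belief.p
    # context drift acts on columns, state transition on rows
    pred = model.P_s @ p @ model.P_theta.T if model.epsilon > 0 else model.P_s @ p
    theta = model.theta_grid
    if x == 1:
        lik = np.vstack([theta, np.ones_like(theta)])
    else:
        lik = np.vstack([1.0 - theta, np.zeros_like(theta)])
    post = pred * lik
    Z = post.sum()
    if Z <= 0.0:
        raise InconsistentBeliefError(
            f"observation x={x} impossible under current belief"
        )
    return BeliefState(post / Z)


def estimates(belief: BeliefState, theta_grid: np.ndarray | None = None) -> Estimates:
    """Posterior means of state and context; the grid defaults to {j/m}."""
    m = belief.p.shape[1]
    grid = np.arange(m) / m if theta_grid is None else np.asarray(theta_grid)
    s_hat = float(belief.p[1].sum())
    theta_hat = float(belief.context_marginal @ grid)
    return Estimates(s_hat=s_hat, theta_hat=theta_hat)


def reset_after_feedback(
    belief: BeliefState, known_prev_state: int, model: BayesModel
) -> BeliefState:
    """Trial-boundary reset: the outcome reveals the previous state, so the
    new trial starts certainly unsafe with the context marginal conditioned
    on that revealed state."""
    if known_prev_state not in (0, 1):
        raise ValueError("known_prev_state must be 0 or 1")
    cond = belief.p[known_prev_state]
    Z = cond.sum()
    if Z <= 0.0:
        raise InconsistentBeliefError(
            f"zero posterior mass on revealed state s={known_prev_state}"
        )
    p = np.zeros_like(belief.p)
    p[0] = cond / Z
    return BeliefState(p)


# -- reward-rate curves and the waiting-time policy --------------------------


def reward_rate_curve(theta: float, model: BayesModel) -> RewardRateCurve:
    """Success probability, expected duration and reward rate of the
    "wait for tau consecutive go cues" strategy, for tau = 1..tau_max."""
    if not (0.0 <= theta < 1.0):
        raise ValueError("theta must be in [0, 1)")
    lam = model.lambda_
    b = (1.0 - lam) * theta
    c = (1.0 - lam) * (1.0 - theta)
    tau = np.arange(1, model.tau_max + 1)
    k = np.arange(model.tau_max)
    bk = b ** k  # b^0 .. b^(tau_max-1)
    S = np.cumsum(bk)  # S[tau-1] = sum_{k<tau} b^k
    denom = 1.0 - c * S
    R = lam * S / denom
    # numerator of Eq for T: tau b^tau + sum_{k<tau} b^k (tau lam + c(k+1))
    btau = b ** tau
    ck1 = np.cumsum(bk * c * (k + 1))  # sum_{k<tau} b^k c (k+1)
    T = (tau * btau + tau * lam * S + ck1) / denom
    r = R / (T + model.T_iti)
    return RewardRateCurve(theta=theta, b=b, c=c, tau=tau, R=R, T=T, r=r)


def reward_rate_curve_printed(theta: float, model: BayesModel) -> RewardRateCurve:
    """Variant using the textbook-printed success-probability numerator
    (1 - b^tau); kept for comparison only -- it exceeds 1 at theta = 0 and is
    contradicted by Monte Carlo simulation of the chain."""
    curve = reward_rate_curve(theta, model)
    lam = model.lambda_
    b, c = curve.b, curve.c
    k = np.arange(model.tau_max)
    S = np.cumsum(b ** k)
    R = (1.0 - b ** curve.tau) / (1.0 - c * S)
    return RewardRateCurve(
        theta=theta, b=b, c=c, tau=curve.tau, R=R, T=curve.T,
        r=R / (curve.T + model.T_iti),
    )


def simulate_chain(
    theta: float,
    lambda_: float,
    tau: int,
    n_trials: int,
    rng: np.random.Generator,
    max_steps: int = 100000,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte Carlo oracle for the go-run chain: per step the unsafe state
    transitions w.p. lambda (then all cues are go); otherwise the cue is go
    w.p. theta or nogo (resetting the run). The trial ends when the run
    reaches ``tau``. Returns (success array, duration array)."""
    success = np.zeros(n_trials, dtype=bool)
    duration = np.zeros(n_trials, dtype=np.int64)
    safe = np.zeros(n_trials, dtype=bool)
    run = np.zeros(n_trials, dtype=np.int64)
    alive = np.ones(n_trials, dtype=bool)
    steps = np.zeros(n_trials, dtype=np.int64)
    for _ in range(max_steps):
        if not alive.any():
            break
        n_alive = int(alive.sum())
        trans = rng.random(n_alive) < lambda_
        go_draw = rng.random(n_alive) < theta
        idx = np.flatnonzero(alive)
        newly_safe = ~safe[idx] & trans
        safe[idx[newly_safe]] = True
        go = safe[idx] | go_draw
        run[idx[go]] += 1
        run[idx[~go]] = 0
        steps[idx] += 1
        done = run[idx] >= tau
        d = idx[done]
        success[d] = safe[d]
        duration[d] = steps[d]
        alive[d] = False
    if alive.any():
        raise RuntimeError("chain simulation exceeded max_steps")
    return success, duration


def optimal_tau(theta: float, model: BayesModel) -> int:
    """Smallest tau maximizing r(tau; theta) over 1..tau_max."""
    curve = reward_rate_curve(theta, model)
    tau_star = int(np.argmax(curve.r)) + 1
    if tau_star == model.tau_max:
        raise ValueError(
            f"argmax of reward rate hit tau_max={model.tau_max}; raise the cap"
        )
    return tau_star


def expected_optimal_tau(belief: BeliefState, model: BayesModel) -> int:
    """argmax over tau of the belief-averaged reward rate <r(tau; theta)>."""
    w = belief.context_marginal
    r_table = _r_table(model)
    mix = w @ r_table
    tau_star = int(np.argmax(mix)) + 1
    if tau_star == model.tau_max:
        raise ValueError(
            f"argmax of expected reward rate hit tau_max={model.tau_max}"
        )
    return tau_star


def safe_posterior_after_run(theta: float, tau: int, model: BayesModel) -> float:
    """P(s=1 | theta, nogo followed by tau go cues): the known-context (m=1)
    filter run on the sequence (0, 1, 1, ..., 1)."""
    sub = BayesModel(
        lambda_=model.lambda_, epsilon=0.0, m=1, T_iti=model.T_iti,
        tau_max=model.tau_max, theta_grid=np.array([theta]),
    )
    belief = BeliefState(np.array([[1.0], [0.0]]))  # right after the nogo
    for _ in range(tau):
        belief = belief_update(belief, 1, sub)
    return float(belief.p[1, 0])


def belief_threshold(belief: BeliefState, tau_star: int, model: BayesModel) -> float:
    """Adaptive threshold s*: the context-marginal average of the safe-state
    posterior reached after tau* consecutive go cues from a nogo."""
    w = belief.context_marginal
    vals = np.array(
        [safe_posterior_after_run(th, tau_star, model) for th in model.theta_grid]
    )
    return float(w @ vals)


def decide(belief: BeliefState, model: BayesModel) -> PolicyDecision:
    """Deterministic act/wait rule: act iff s_hat - s* >= 0."""
    tau_star = expected_optimal_tau(belief, model)
    s_thr = belief_threshold(belief, tau_star, model)
    s_hat = float(belief.p[1].sum())
    delta = s_hat - s_thr
    return PolicyDecision(
        tau_star_expected=tau_star, s_threshold=s_thr, delta=delta, act=delta >= 0.0
    )


# -- cached tables -----------------------------------------------------------

_r_cache: dict[tuple, np.ndarray] = {}
_psafe_cache: dict[tuple, np.ndarray] = {}


def _model_key(model: BayesModel) -> tuple:
    return (model.lambda_, model.T_iti, model.tau_max, tuple(model.theta_grid))


def _r_table(model: BayesModel) -> np.ndarray:
    """(m, tau_max) table of r(tau; theta_j)."""
    key = _model_key(model)
    if key not in _r_cache:
        _r_cache[key] = np.vstack(
            [reward_rate_curve(th, model).r for th in model.theta_grid]
        )
    return _r_cache[key]


def _psafe_table(model: BayesModel) -> np.ndarray:
    """(m, tau_max+1) table of P(s=1 | theta_j, nogo + tau gos)."""
    key = _model_key(model)
    if key not in _psafe_cache:
        tbl = np.zeros((model.m, model.tau_max + 1))
        for j, th in enumerate(model.theta_grid):
            sub = BayesModel(
                lambda_=model.lambda_, epsilon=0.0, m=1, T_iti=model.T_iti,
                tau_max=model.tau_max, theta_grid=np.array([th]),
            )
            belief = BeliefState(np.array([[1.0], [0.0]]))
            for tau in range(1, model.tau_max + 1):
                belief = belief_update(belief, 1, sub)
                tbl[j, tau] = belief.p[1, 0]
        _psafe_cache[key] = tbl
    return _psafe_cache[key]


# -- closed-loop agent -------------------------------------------------------


class BayesAgent:
    """Ideal observer driving the waiting-time policy in closed loop.

    The belief is filtered through every step (inter-trial intervals share
    unsafe-cue statistics, so they remain informative about the context); at
    each trial end the environment's feedback reveals the previous state and
    the belief is reset accordingly.
    """

    def __init__(self, model: BayesModel, record: bool = True) -> None:
        self.model = model
        self.belief = BeliefState.initial(model)
        self.record = record
        self.trace: list[dict] = []
        self._r_tbl = _r_table(model)
        self._ps_tbl = _psafe_table(model)

    def _decide_fast(self) -> PolicyDecision:
        w = self.belief.context_marginal
        mix = w @ self._r_tbl
        tau_star = int(np.argmax(mix)) + 1
        if tau_star == self.model.tau_max:
            raise ValueError("expected optimal tau hit tau_max")
        s_thr = float(w @ self._ps_tbl[:, tau_star])
        s_hat = float(self.belief.p[1].sum())
        delta = s_hat - s_thr
        return PolicyDecision(tau_star, s_thr, delta, delta >= 0.0)

    def step(self, x: int, prev_reward: float) -> int:
        self.belief = belief_update(self.belief, x, self.model)
        d = self._decide_fast()
        if self.record:
            est_theta = float(self.belief.context_marginal @ self.model.theta_grid)
            self.trace.append(
                {
                    "s_hat": float(self.belief.p[1].sum()),
                    "theta_hat": est_theta,
                    "tau_star": d.tau_star_expected,
                    "s_threshold": d.s_threshold,
                    "delta": d.delta,
                    "act": int(d.act),
                }
            )
        return int(d.act)

    def notify_trial_end(self, outcome: str) -> None:
        # reward feedback reveals the state: rewarded/timeout -> was safe,
        # premature -> was unsafe
        known = 1 if outcome in ("rewarded", "timeout") else 0
        self.belief = reset_after_feedback(self.belief, known, self.model)


def run_bayes_agent(
    config: TaskConfig,
    model: BayesModel,
    n_trials: int,
    rng: np.random.Generator | None = None,
    record: bool = True,
) -> tuple[SessionLog, list[dict]]:
    """Closed loop of the ideal observer with the task environment."""
    agent = BayesAgent(model, record=record)
    env = ChangeDetectionEnv(config, n_trials, rng=rng, record_steps=record)
    log = env.run(agent)
    return log, agent.trace
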