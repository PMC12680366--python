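"""Heuristic drift-diffusion agents and the constrained linear-output model.

The disjoint-integrator heuristic replaces the joint posterior with two
scalar recursions: a leaky running average of the cue stream estimates the
context,

    theta_tilde_t = alpha * theta_tilde_{t-1} + (1 - alpha) * x_t,

and an integrate-with-reset accumulator estimates the state by climbing at
rate 1/tau*(theta_tilde) on each go cue and resetting to zero on each nogo;
the agent acts when the accumulator reaches 1. Because the running average
cannot tell misleading go cues (unsafe) from reliable ones (safe), it
systematically overestimates the true context.

The linear-output model (z_t = alpha z_{t-1} + (1-alpha) x_t,
Q_t = beta z_t + eps) is the constrained regression used to test whether an
agent's output trace is explainable by plain leaky integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .bayes import BayesModel, optimal_tau
from .task import ChangeDetectionEnv, SessionLog, TaskConfig

__all__ = [
    "IntegratorState",
    "LinearOutputModel",
    "leaky_theta_update",
    "reset_integrator_update",
    "DisjointIntegratorAgent",
    "run_ddm_agent",
    "ALPHA_SWEEP",
    "fit_linear_output",
    "simulate_linear_output",
]

# the published alpha grid for the performance sweep
ALPHA_SWEEP = (
    0.85, 0.875, 0.9, 0.925, 0.95, 0.96, 0.97, 0.98, 0.99,
    0.991, 0.992, 0.993, 0.994, 0.995,
)


@dataclass
class IntegratorState:
    theta_tilde: float = 0.5  # uninformative midpoint at start
    s_tilde: float = 0.0
    alpha: float = 0.95


@dataclass
class LinearOutputModel:
    alpha: float
    beta: float
    eps0: float
    eps_by_context: dict | None = None
    r2_fit: float = 0.0


def leaky_theta_update(state: IntegratorState, x: int) -> IntegratorState:
    """Leaky running average of the binary cue stream."""
    if x not in (0, 1):
        raise ValueError("x must be 0 or 1")
    th = state.alpha * state.theta_tilde + (1.0 - state.alpha) * x
    return IntegratorState(theta_tilde=th, s_tilde=state.s_tilde, alpha=state.alpha)


def reset_integrator_update(
    state: IntegratorState, x: int, tau_star_lookup
) -> IntegratorState:
    """Integrate-with-reset state accumulator: +1/tau*(theta_tilde) per go,
    hard reset on nogo; the action threshold is s_tilde >= 1."""
    if x == 1:
        s = state.s_tilde + 1.0 / tau_star_lookup(state.theta_tilde)
    else:
        s = 0.0
    return IntegratorState(theta_tilde=state.theta_tilde, s_tilde=s, alpha=state.alpha)


class DisjointIntegratorAgent:
    """Two disjoint scalar integrators standing in for the joint posterior.

    ``tau*`` is looked up on the model's context grid (nearest grid value by
    default, linear interpolation optionally).
    """

    def __init__(
        self,
        alpha: float,
        model: BayesModel,
        theta_init: float = 0.5,
        update_during_iti: bool = True,
        interpolate: bool = False,
    ) -> None:
        if not (0.0 < alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        self.alpha = alpha
        self.model = model
        self.update_during_iti = update_during_iti
        self.interpolate = interpolate
        self._grid = np.asarray(model.theta_grid, dtype=float)
        self._tau_tbl = np.array(
            [optimal_tau(th, model) for th in self._grid], dtype=float
        )
        self.state = IntegratorState(theta_tilde=theta_init, alpha=alpha)

    def tau_star(self, theta_tilde: float) -> float:
        if self.interpolate and len(self._grid) > 1:
            return float(np.interp(theta_tilde, self._grid, self._tau_tbl))
        j = int(np.argmin(np.abs(self._grid - theta_tilde)))
        return float(self._tau_tbl[j])

    def step(self, x: int, prev_reward: float) -> int:
        st = leaky_theta_update(self.state, x)
        st = reset_integrator_update(st, x, self.tau_star)
        self.state = st
        return int(st.s_tilde >= 1.0)


def run_ddm_agent(
    config: TaskConfig,
    alpha: float,
    model: BayesModel,
    n_trials: int,
    rng: np.random.Generator | None = None,
    theta_init: float = 0.5,
    record_steps: bool = False,
) -> SessionLog:
    """Closed loop of the disjoint-integrator agent with the environment."""
    agent = DisjointIntegratorAgent(alpha, model, theta_init=theta_init)
    env = ChangeDetectionEnv(config, n_trials, rng=rng, record_steps=record_steps)
    return env.run(agent)


# -- linear-output model fitting ---------------------------------------------


def simulate_linear_output(
    x_trace: np.ndarray,
    alpha: float,
    beta: float,
    eps0: float,
    z0: float = 0.0,
) -> np.ndarray:
    """Generate Q_t = beta z_t + eps0 from the leaky recursion."""
    z = _leaky_filter(np.asarray(x_trace, dtype=float), alpha, z0)
    return beta * z + eps0


def _leaky_filter(x: np.ndarray, alpha: float, z0: float = 0.0) -> np.ndarray:
    from scipy.signal import lfilter

    z, _ = lfilter([1.0 - alpha], [1.0, -alpha], x, zi=[alpha * z0])
    return z


def fit_linear_output(
    q_trace: np.ndarray,
    x_trace: np.ndarray,
    fit_window: int = 100_000,
    context_labels: np.ndarray | None = None,
) -> LinearOutputModel:
    """Constrained fit of the leaky-integrator output model to a trace.

    Parameters are constrained to 0 < alpha < 1, beta > 0 and baseline(s) > 0.
    The fit uses the first ``fit_window`` steps; the variance explained
    (``r2_fit``) is evaluated on the entire trace. With ``context_labels`` a
    separate baseline eps_theta is fitted per context.
    """
    q = np.asarray(q_trace, dtype=float)
    x = np.asarray(x_trace, dtype=float)
    if q.shape != x.shape or q.ndim != 1:
        raise ValueError("q_trace and x_trace must be 1-d and aligned")
    n = len(q)
    if n < fit_window:
        warnings.warn(
            f"trace ({n} steps) shorter than fit window ({fit_window}); "
            "fitting on the full trace"
        )
    w = min(n, fit_window)

    if context_labels is not None:
        labels = np.asarray(context_labels)
        uniq = np.unique(labels)
        onehot = (labels[:, None] == uniq[None, :]).astype(float)
    else:
        uniq = None
        onehot = np.ones((n, 1))

    lo = 1e-6

    def _solve(alpha: float):
        z = _leaky_filter(x, alpha)
        A = np.column_stack([z[:w], onehot[:w]])
        coef, _ = optimize.nnls(A, q[:w])
        coef = np.maximum(coef, lo)  # keep strictly inside the constraint box
        resid = q[:w] - A @ coef
        return float(resid @ resid), coef, z

    res = optimize.minimize_scalar(
        lambda a: _solve(a)[0], bounds=(lo, 1.0 - lo), method="bounded",
        options={"xatol": 1e-10},
    )
    alpha = float(res.x)
    _, coef, z = _solve(alpha)
    beta = float(coef[0])
    baselines = coef[1:]

    pred = beta * z + onehot @ baselines
    ss_res = float(np.sum((q - pred) ** 2))
    var = float(np.var(q)) * n
    if var <= 0.0:
        warnings.warn("zero-variance target; r^2 defined as 0")
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / var

    eps_by_context = (
        {float(u): float(e) for u, e in zip(uniq, baselines)} if uniq is not None else None
    )
    return LinearOutputModel(
        alpha=alpha,
        beta=beta,
        eps0=float(baselines[0]) if uniq is None else float(np.mean(baselines)),
        eps_by_context=eps_by_context,
        r2_fit=r2,
    )
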