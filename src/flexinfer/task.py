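"""Discrete-time change-detection environment with latent context.

The agent must detect a hidden transition from an *unsafe* to a *safe* state
using a single stream of binary go/nogo cues. In the safe state every cue is
go; in every other phase a go occurs with probability ``theta``, the latent
context (cue unreliability), which is constant within a block of trials and
switches between blocks. Acting in the safe state is rewarded; acting earlier
is premature.

Two dialects share the same integer-step machinery:

* ``network`` -- the training environment for recurrent agents: unsafe
  duration exponential (mean 10 steps, floor 1), forced nogo on the first
  step of each trial, inter-trial interval uniform on 5..25 steps, optional
  premature penalty.
* ``mouse`` -- the head-fixed experiment timing at 0.2 s bins: unsafe
  duration 4 + floor(Exp(rate 0.1)) bins, a 35-bin cap on the safe state
  (timeout), a 35-bin premature phase after an early lick, ITI uniform on
  5..25 bins (1-5 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "EnvState",
    "StepRecord",
    "TrialRecord",
    "SessionLog",
    "BlockSchedule",
    "make_block_schedule",
    "emission",
    "markov_context_step",
    "ChangeDetectionEnv",
    "env_step",
    "run_session",
    "session_to_frame",
    "session_from_frame",
    "write_session_csv",
    "read_session_csv",
    "write_step_trace",
]

UNSAFE, SAFE, PREMATURE, ITI = "unsafe", "safe", "premature", "iti"
OUTCOMES = ("rewarded", "premature", "timeout", "no_action")


@dataclass
class TaskConfig:
    """Environment parameters; defaults follow the network-training dialect."""

    lambda_: float = 0.1
    theta_set: tuple[float, ...] = (0.3, 0.7)
    block_length_range: tuple[int, int] = (30, 100)
    dialect: str = "network"
    iti_range: tuple[int, int] = (5, 25)
    unsafe_mean_steps: float = 10.0
    forced_first_nogo: bool = True
    premature_lockout: int = 35  # mouse dialect: 7 s at 0.2 s bins
    safe_cap: int = 35  # mouse dialect: 7 s
    reward_correct: float = 1.0
    penalty_premature: float = -3.0
    training: bool = False  # apply premature penalty only when training
    max_trial_steps: int = 1000  # network dialect: no_action guard
    iti_actions_ignored: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.lambda_ <= 1.0):
            raise ValueError(f"lambda_ must be in (0, 1], got {self.lambda_}")
        if len(self.theta_set) == 0:
            raise ValueError("theta_set must be non-empty")
        for th in self.theta_set:
            # theta = 1 is allowed (cues carry no information in the unsafe
            # state); the default network-training grid includes it
            if not (0.0 <= th <= 1.0):
                raise ValueError(f"theta values must be in [0, 1], got {th}")
        lo, hi = self.iti_range
        if not (0 < lo <= hi):
            raise ValueError(f"iti_range must be positive and ordered, got {self.iti_range}")
        if self.unsafe_mean_steps < 1:
            raise ValueError("unsafe_mean_steps must be >= 1")
        if self.dialect not in ("network", "mouse"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "TaskConfig":
        d = json.loads(text)
        for k in ("theta_set", "block_length_range", "iti_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class EnvState:
    phase: str = UNSAFE
    theta_current: float = 0.0
    consec_go: int = 0
    step_index: int = 0
    trial_index: int = 0
    block_index: int = 0
    scheduled_transition_step: int = 0  # trial step at which unsafe -> safe
    step_in_trial: int = 0
    phase_steps_left: int = 0  # countdown inside premature / iti / safe cap


@dataclass
class StepRecord:
    x: int
    a: int
    r: float
    s_true: int
    theta_true: float
    phase: str
    consec_go: int = 0


@dataclass
class TrialRecord:
    theta: float
    block_index: int
    trial_index: int
    waiting_time_tau: int
    outcome: str
    duration_steps: int
    steps: list[StepRecord] = field(default_factory=list)


@dataclass
class SessionLog:
    trials: list[TrialRecord]
    block_schedule: list[tuple[float, int]]
    config: TaskConfig | None = None


BlockSchedule = list  # list of (theta, length) pairs


def make_block_schedule(
    theta_set: Sequence[float],
    block_length_range: tuple[int, int],
    n_trials: int,
    rng: np.random.Generator,
) -> BlockSchedule:
    """Random block schedule: per-block theta drawn from ``theta_set`` with
    no immediate repeats, lengths uniform in ``block_length_range``; the last
    block is truncated so the total equals ``n_trials``."""
    theta_set = list(theta_set)
    if len(theta_set) == 0:
        raise ValueError("theta_set must be non-empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    lo, hi = block_length_range
    schedule: BlockSchedule = []
    remaining = n_trials
    prev = None
    while remaining > 0:
        if len(theta_set) == 1:
            theta = theta_set[0]
        else:
            choices = [t for t in theta_set if t != prev]
            theta = choices[rng.integers(len(choices))]
        length = int(rng.integers(lo, hi + 1))
        length = min(length, remaining)
        schedule.append((theta, length))
        remaining -= length
        prev = theta
    return schedule


def emission(phase: str, theta: float, rng: np.random.Generator) -> int:
    """One binary cue: always go in the safe phase, else go w.p. theta."""
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    if phase == SAFE:
        return 1
    return int(rng.random() < theta)


def markov_context_step(
    theta_index: int, epsilon: float, m: int, rng: np.random.Generator
) -> int:
    """Symmetric Markov drift on an m-point context grid: stay w.p. 1-eps,
    otherwise jump uniformly to one of the other m-1 grid values."""
    if not (0.0 <= epsilon < 1.0):
        raise ValueError(f"epsilon must be in [0, 1), got {epsilon}")
    if m < 2 and epsilon > 0:
        raise ValueError("m must be >= 2 when epsilon > 0")
    if epsilon == 0.0 or rng.random() >= epsilon:
        return theta_index
    j = int(rng.integers(m - 1))
    return j if j < theta_index else j + 1


class ChangeDetectionEnv:
    """Stateful stepping interface over the change-detection task.

    Usage per step: ``x = env.observe()`` then ``reward, trial_ended = env.act(a)``.
    ``env.finished_trial`` holds the completed :class:`TrialRecord` when a
    trial just ended.
    """

    def __init__(
        self,
        config: TaskConfig,
        n_trials: int,
        rng: np.random.Generator | None = None,
        schedule: BlockSchedule | None = None,
        record_steps: bool = True,
    ) -> None:
        self.config = config
        self.n_trials = n_trials
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        if schedule is None:
            schedule = make_block_schedule(
                config.theta_set, config.block_length_range, n_trials, self.rng
            )
        self.schedule = schedule
        self._block_theta = []
        self._block_of_trial = []
        for b, (theta, length) in enumerate(schedule):
            self._block_theta.extend([theta] * length)
            self._block_of_trial.extend([b] * length)
        if len(self._block_theta) < n_trials:
            raise ValueError("schedule covers fewer trials than n_trials")
        self.record_steps = record_steps
        self.state = EnvState()
        self.trials: list[TrialRecord] = []
        self.finished_trial: TrialRecord | None = None
        self._cur_steps: list[StepRecord] = []
        self._cur_tau = 0
        self._pending_obs: int | None = None
        self._start_trial(0)

    # -- internal bookkeeping ------------------------------------------------

    def _draw_unsafe_duration(self) -> int:
        cfg = self.config
        if cfg.dialect == "network":
            d = self.rng.exponential(cfg.unsafe_mean_steps)
            return max(1, int(round(d)))
        # mouse: 0.8 s + 0.2 s * floor(x), x ~ Exp(rate 0.1), in 0.2 s bins
        x = self.rng.exponential(1.0 / cfg.lambda_)
        return 4 + int(np.floor(x))

    def _draw_iti(self) -> int:
        lo, hi = self.config.iti_range
        return int(self.rng.integers(lo, hi + 1))

    def _start_trial(self, trial_index: int) -> None:
        s = self.state
        s.trial_index = trial_index
        s.block_index = self._block_of_trial[trial_index]
        s.theta_current = self._block_theta[trial_index]
        s.phase = UNSAFE
        s.step_in_trial = 0
        s.scheduled_transition_step = self._draw_unsafe_duration()
        self._cur_steps = []
        self._cur_tau = 0
        self._cur_len = 0

    def _end_trial(self, outcome: str) -> None:
        s = self.state
        rec = TrialRecord(
            theta=s.theta_current,
            block_index=s.block_index,
            trial_index=s.trial_index,
            waiting_time_tau=self._cur_tau,
            outcome=outcome,
            duration_steps=self._cur_len,
            steps=self._cur_steps if self.record_steps else [],
        )
        self.trials.append(rec)
        self.finished_trial = rec
        s.phase = ITI
        s.phase_steps_left = self._draw_iti()
        # a block switch takes effect at the trial boundary: the ITI that
        # separates two trials already carries the upcoming trial's context
        nxt = s.trial_index + 1
        if nxt < self.n_trials:
            s.theta_current = self._block_theta[nxt]

    @property
    def done(self) -> bool:
        return len(self.trials) >= self.n_trials

    # -- public stepping -----------------------------------------------------

    def observe(self) -> int:
        """Emit the observation for the current step (before the action)."""
        s, cfg = self.state, self.config
        if s.phase == UNSAFE and s.step_in_trial >= s.scheduled_transition_step:
            s.phase = SAFE
            s.phase_steps_left = cfg.safe_cap
        if (
            s.phase == UNSAFE
            and s.step_in_trial == 0
            and cfg.dialect == "network"
            and cfg.forced_first_nogo
        ):
            x = 0
        else:
            x = emission(s.phase, s.theta_current, self.rng)
        if x == 1:
            s.consec_go += 1
        else:
            s.consec_go = 0
        self._pending_obs = x
        return x

    def act(self, action: int) -> tuple[float, bool]:
        """Apply the agent's action for the current step; returns (reward,
        trial_ended). Must follow :meth:`observe`."""
        if action not in (0, 1):
            raise ValueError(f"action must be 0 or 1, got {action}")
        if self._pending_obs is None:
            raise RuntimeError("act() called before observe()")
        x = self._pending_obs
        self._pending_obs = None
        s, cfg = self.state, self.config
        self.finished_trial = None
        r = 0.0
        trial_ended = False

        phase_now = s.phase
        in_trial = phase_now in (UNSAFE, SAFE)
        if in_trial:
            self._cur_tau = s.consec_go
            self._cur_len += 1
            if action == 1:
                if phase_now == SAFE:
                    r = cfg.reward_correct
                    self._record(x, action, r, phase_now)
                    self._end_trial("rewarded")
                    trial_ended = True
                else:  # premature
                    if cfg.dialect == "network":
                        r = cfg.penalty_premature if cfg.training else 0.0
                        self._record(x, action, r, phase_now)
                        self._end_trial("premature")
                        trial_ended = True
                    else:
                        self._record(x, action, 0.0, phase_now)
                        self._end_trial("premature")
                        trial_ended = True
                        # replace the ITI countdown with lockout + ITI
                        s.phase = PREMATURE
                        s.phase_steps_left = cfg.premature_lockout
            else:
                self._record(x, action, 0.0, phase_now)
                s.step_in_trial += 1
                if phase_now == SAFE:
                    s.phase_steps_left -= 1
                    if cfg.dialect == "mouse" and s.phase_steps_left <= 0:
                        self._end_trial("timeout")
                        trial_ended = True
                if (
                    not trial_ended
                    and cfg.dialect == "network"
                    and s.step_in_trial >= cfg.max_trial_steps
                ):
                    self._end_trial("no_action")
                    trial_ended = True
        else:  # premature lockout or ITI: actions ignored
            self._record(x, action, 0.0, phase_now)
            s.phase_steps_left -= 1
            if s.phase_steps_left <= 0:
                if s.phase == PREMATURE:
                    s.phase = ITI
                    s.phase_steps_left = self._draw_iti()
                elif not self.done:
                    self._start_trial(s.trial_index + 1)

        s.step_index += 1
        return r, trial_ended

    def _record(self, x: int, a: int, r: float, phase: str) -> None:
        if not self.record_steps:
            return
        s = self.state
        self._cur_steps.append(
            StepRecord(
                x=x,
                a=a,
                r=r,
                s_true=int(phase == SAFE),
                theta_true=s.theta_current,
                phase=phase,
                consec_go=s.consec_go,
            )
        )

    def run(self, agent, max_steps: int | None = None) -> SessionLog:
        """Closed loop with an agent exposing ``step(x, prev_reward) -> action``
        and optionally ``notify_trial_end(outcome)``."""
        prev_r = 0.0
        steps = 0
        while not self.done:
            x = self.observe()
            a = int(agent.step(x, prev_r))
            prev_r, ended = self.act(a)
            if ended and hasattr(agent, "notify_trial_end"):
                agent.notify_trial_end(self.trials[-1].outcome)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        return SessionLog(
            trials=list(self.trials), block_schedule=list(self.schedule), config=self.config
        )


def env_step(
    env: ChangeDetectionEnv, action: int
) -> tuple[EnvState, StepRecord]:
    """Single observe+act step; returns the new state and the step record."""
    x = env.observe()
    r, _ = env.act(action)
    s = env.state
    rec = StepRecord(
        x=x,
        a=action,
        r=r,
        s_true=int(s.phase == SAFE),
        theta_true=s.theta_current,
        phase=s.phase,
        consec_go=s.consec_go,
    )
    return s, rec


def run_session(
    agent,
    config: TaskConfig,
    n_trials: int,
    rng: np.random.Generator | None = None,
    record_steps: bool = True,
) -> SessionLog:
    """Run ``agent`` through ``n_trials`` trials; all randomness derives from
    ``rng`` (or ``config.seed``) so a session replays bit-identically."""
    env = ChangeDetectionEnv(config, n_trials, rng=rng, record_steps=record_steps)
    try:
        return env.run(agent)
    except Exception as exc:
        raise RuntimeError(
            f"agent failed at trial {env.state.trial_index} "
            f"(step {env.state.step_index})"
        ) from exc


# -- session I/O (one CSV row per trial) -------------------------------------

_TRIAL_COLS = [
    "trial_index",
    "block_index",
    "theta",
    "waiting_time_tau",
    "outcome",
    "duration_steps",
]


def session_to_frame(session: SessionLog) -> pd.DataFrame:
    rows = [
        {
            "trial_index": t.trial_index,
            "block_index": t.block_index,
            "theta": t.theta,
            "waiting_time_tau": t.waiting_time_tau,
            "outcome": t.outcome,
            "duration_steps": t.duration_steps,
        }
        for t in session.trials
    ]
    return pd.DataFrame(rows, columns=_TRIAL_COLS)


def session_from_frame(df: pd.DataFrame) -> SessionLog:
    trials = [
        TrialRecord(
            theta=float(r.theta),
            block_index=int(r.block_index),
            trial_index=int(r.trial_index),
            waiting_time_tau=int(r.waiting_time_tau),
            outcome=str(r.outcome),
            duration_steps=int(r.duration_steps),
        )
        for r in df.itertuples(index=False)
    ]
    schedule: BlockSchedule = []
    for t in trials:
        if schedule and schedule[-1][0] == t.theta and schedule[-1][2] == t.block_index:
            schedule[-1][1] += 1
        else:
            schedule.append([t.theta, 1, t.block_index])
    return SessionLog(
        trials=trials, block_schedule=[(th, n) for th, n, _ in schedule], config=None
    )


def write_session_csv(session: SessionLog, path) -> None:
    session_to_frame(session).to_csv(path, index=False)


def read_session_csv(path) -> SessionLog:
    return session_from_frame(pd.read_csv(path))


def write_step_trace(session: SessionLog, path) -> None:
    """JSON-lines per-step trace (one object per step)."""
    with open(path, "w") as fh:
        for t in session.trials:
            for rec in t.steps:
                fh.write(
                    json.dumps(
                        {
                            "trial_index": t.trial_index,
                            "x": rec.x,
                            "a": rec.a,
                            "r": rec.r,
                            "s_true": rec.s_true,
                            "theta_true": rec.theta_true,
                            "phase": rec.phase,
                        }
                    )
                    + "\n"
                )
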