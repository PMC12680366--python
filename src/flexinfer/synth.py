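"""Synthetic behavioral sessions with known adaptation structure.

Emulates the statistical shape of rodent session logs -- blocked context
schedules, context-dependent mean waiting times, trial-to-trial noise and a
configurable adaptation lag -- so that the behavioral analyses can be tested
against a known ground truth. The generator does not simulate cue streams or
lick kinematics: each trial's waiting time is drawn directly from a
discretized truncated-normal around the target mean of the *effective*
context, which lags the true block context by ``adaptation_lag`` trials (a
lag of 0 is an inference-driven adapter, a lag of 1 the signature of a
feedback-driven learner).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import SessionLog, TrialRecord

__all__ = ["SynthBehaviorParams", "generate_session", "generate_cohort"]


@dataclass
class SynthBehaviorParams:
    tau_mean_by_theta: dict = field(
        default_factory=lambda: {0.3: 4.0, 0.7: 8.0}
    )
    tau_noise_sd: float = 1.5
    adaptation_lag: int = 0
    n_subjects: int = 7
    n_blocks: int = 10
    block_length_range: tuple[int, int] = (30, 60)
    subject_effect_sd: float = 0.0  # optional subject-level heterogeneity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adaptation_lag < 0:
            raise ValueError("adaptation_lag must be >= 0")
        for theta, mu in self.tau_mean_by_theta.items():
            if mu <= 0:
                raise ValueError(f"tau mean for theta={theta} must be positive")


def _draw_tau(mean: float, sd: float, rng: np.random.Generator) -> int:
    """Discretized positive noise around the target mean."""
    if sd == 0.0:
        return int(round(mean))
    tau = rng.normal(mean, sd)
    return int(max(0, round(tau)))


def generate_session(
    params: SynthBehaviorParams,
    rng: np.random.Generator,
    subject_shift: float = 0.0,
) -> SessionLog:
    """One session: blocked theta schedule, per-trial waiting times drawn
    around the lagged-effective context's target mean."""
    thetas = sorted(params.tau_mean_by_theta)
    lo, hi = params.block_length_range
    schedule: list[tuple[float, int]] = []
    prev = None
    for _ in range(params.n_blocks):
        if len(thetas) == 1:
            theta = thetas[0]
        else:
            choices = [t for t in thetas if t != prev]
            theta = choices[rng.integers(len(choices))]
        schedule.append((theta, int(rng.integers(lo, hi + 1))))
        prev = theta
    trials: list[TrialRecord] = []
    idx = 0
    prev_theta = None
    for block_index, (theta, length) in enumerate(schedule):
        for k in range(length):
            if k < params.adaptation_lag and prev_theta is not None:
                eff_theta = prev_theta
            else:
                eff_theta = theta
            mu = params.tau_mean_by_theta[eff_theta] + subject_shift
            tau = _draw_tau(max(mu, 0.5), params.tau_noise_sd, rng)
            trials.append(
                TrialRecord(
                    theta=theta,
                    block_index=block_index,
                    trial_index=idx,
                    waiting_time_tau=tau,
                    outcome="rewarded",
                    duration_steps=tau + 1,
                )
            )
            idx += 1
        prev_theta = theta
    return SessionLog(
        trials=trials,
        block_schedule=[(th, ln) for th, ln in schedule],
        config=None,
    )


def generate_cohort(
    params: SynthBehaviorParams,
    n_subjects: int | None = None,
    rng: np.random.Generator | None = None,
    sessions_per_subject: int = 1,
) -> list[list[SessionLog]]:
    """Independent per-subject sessions; returns sessions grouped by subject."""
    if n_subjects is None:
        n_subjects = params.n_subjects
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cohort = []
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(rng.integers(2**31))
        shift = (
            sub_rng.normal(0.0, params.subject_effect_sd)
            if params.subject_effect_sd > 0
            else 0.0
        )
        cohort.append(
            [
                generate_session(params, sub_rng, subject_shift=shift)
                for _ in range(sessions_per_subject)
            ]
        )
    return cohort
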