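"""Simple reference agents for the change-detection task.

All agents implement ``step(x, prev_reward) -> action`` and may implement
``notify_trial_end(outcome)``; :func:`flexinfer.task.run_session` drives them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["NeverActAgent", "AlwaysActAgent", "FixedTauAgent", "OracleAgent"]


class NeverActAgent:
    def step(self, x: int, prev_reward: float) -> int:
        return 0


class AlwaysActAgent:
    def step(self, x: int, prev_reward: float) -> int:
        return 1


class FixedTauAgent:
    """Act after exactly ``tau`` consecutive go cues since the last nogo.

    With the context known, this is the optimal policy when ``tau`` equals
    the reward-rate-maximizing waiting time for that context.
    """

    def __init__(self, tau: int) -> None:
        if tau < 1:
            raise ValueError("tau must be >= 1")
        self.tau = tau
        self._run = 0

    def step(self, x: int, prev_reward: float) -> int:
        # mirrors the environment's consecutive-go bookkeeping exactly
        self._run = self._run + 1 if x == 1 else 0
        return int(self._run >= self.tau)


class OracleAgent:
    """Clairvoyant agent that reads the true phase from the environment and
    acts on the first safe step; an upper bound used in sanity checks."""

    def __init__(self, env) -> None:
        self.env = env

    def step(self, x: int, prev_reward: float) -> int:
        return int(self.env.state.phase == "safe")
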