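"""Behavioral and neural analyses.

Behavioral: waiting-time statistics, block-switch adaptation correlations
(does a trial's waiting time track the mean of the block it is in, or the
mean of the preceding block?), paired Wilcoxon contrasts of first-trial
waiting times between contexts, and per-context performance tables.

Neural: PCA of recurrent hidden states, cross-validated decoding of
ground-truth and Bayesian variables from hidden activity (state via logistic
regression, the state estimate via its log-likelihood ratio, context and the
decision variable via linear regression), and planted-stimulus vector
fields that chart how each agent's internal coordinates move in response to
a fixed cue sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.model_selection import KFold

from . import bayes as _bayes
from .bayes import BayesAgent, BayesModel, belief_update, reset_after_feedback
from .integrators import DisjointIntegratorAgent
from .task import ChangeDetectionEnv, SessionLog, TaskConfig

__all__ = [
    "AdaptationCurve",
    "DecodeReport",
    "PCAReport",
    "VectorField",
    "waiting_times",
    "adaptation_correlations",
    "first_trial_contrast",
    "pca_hidden",
    "sllr",
    "decode",
    "bayes_trace_along",
    "vector_field",
    "PLANTED_STIMULUS",
    "performance_table",
]

RESPONDED = ("rewarded", "premature")
SLLR_CLIP = 30.0

# planted 21-step cue sequence: one nogo, eight gos, twelve nogos
PLANTED_STIMULUS = np.array([0] + [1] * 8 + [0] * 12, dtype=int)


@dataclass
class AdaptationCurve:
    positions: np.ndarray  # trial index relative to the switch; +1 = first new
    r_previous: np.ndarray
    r_current: np.ndarray
    n_events: np.ndarray
    crossover_trial: int | None


@dataclass
class DecodeReport:
    target: str
    model_type: str
    cv_scheme: str
    score: float
    fold_scores: np.ndarray


@dataclass
class PCAReport:
    components: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray  # projected data, samples x components


@dataclass
class VectorField:
    stimulus: np.ndarray
    thetas: np.ndarray
    positions: np.ndarray  # (n_theta, len(stimulus), 2) mean projected state
    displacements: np.ndarray  # (n_theta, len(stimulus)-1, 2)
    n_per_theta: int
    axis_names: tuple[str, str]


# -- waiting times -----------------------------------------------------------


def waiting_times(
    session: SessionLog, in_seconds: bool = False
) -> np.ndarray:
    """Per-trial waiting time tau (consecutive go cues at the action) over
    responded trials; non-responders (timeout / no-action) are excluded."""
    taus = np.array(
        [t.waiting_time_tau for t in session.trials if t.outcome in RESPONDED],
        dtype=float,
    )
    return taus * 0.2 if in_seconds else taus


# -- adaptation correlations -------------------------------------------------


def _session_blocks(session: SessionLog, skip_session_head: int = 4):
    """Responded trials grouped by block, after dropping the first trials of
    the session; returns list of (theta, [tau...]) keeping block order and a
    parallel list of per-block trial lists (full, for position lookup)."""
    trials = [
        t
        for i, t in enumerate(session.trials)
        if i >= skip_session_head and t.outcome in RESPONDED
    ]
    blocks: list[list] = []
    for t in trials:
        if blocks and blocks[-1][0] == t.block_index:
            blocks[-1][1].append(t)
        else:
            blocks.append([t.block_index, [t]])
    return [(b[1][0].theta, b[1]) for b in blocks]


def _block_mean(taus: list[float], trim: int = 4) -> float | None:
    """Block mean excluding the first and last ``trim`` trials."""
    core = taus[trim:-trim] if trim > 0 else taus
    if len(core) < 1:
        return None
    return float(np.mean(core))


def adaptation_correlations(
    sessions: list[SessionLog],
    window: int = 4,
    trim: int = 4,
    skip_session_head: int = 4,
) -> AdaptationCurve:
    """Correlation of single-trial waiting times with the previous- vs
    current-block mean, by trial position around each block switch.

    Position -k is the k-th trial before the switch (in the old block),
    position +k the k-th trial of the new block. For every switch event the
    "previous" mean is the old block's and the "current" mean the new
    block's, both computed excluding each block's first and last ``trim``
    trials. The crossover trial is the earliest positive position at which
    the current-block correlation exceeds the previous-block one.
    """
    positions = np.array(
        [p for p in range(-window, window + 1) if p != 0], dtype=int
    )
    per_pos: dict[int, list[tuple[float, float, float]]] = {int(p): [] for p in positions}
    for session in sessions:
        blocks = _session_blocks(session, skip_session_head)
        if len(blocks) < 2:
            continue
        for i in range(1, len(blocks)):
            theta_prev, trials_prev = blocks[i - 1]
            theta_cur, trials_cur = blocks[i]
            m_prev = _block_mean([t.waiting_time_tau for t in trials_prev], trim)
            m_cur = _block_mean([t.waiting_time_tau for t in trials_cur], trim)
            if m_prev is None or m_cur is None:
                warnings.warn("block too short for trimmed mean; skipping event")
                continue
            for p in positions:
                if p < 0:
                    idx = len(trials_prev) + p
                    trial = trials_prev[idx] if idx >= 0 else None
                else:
                    trial = trials_cur[p - 1] if p - 1 < len(trials_cur) else None
                if trial is not None:
                    per_pos[int(p)].append(
                        (float(trial.waiting_time_tau), m_prev, m_cur)
                    )
    r_prev = np.full(len(positions), np.nan)
    r_cur = np.full(len(positions), np.nan)
    n_events = np.zeros(len(positions), dtype=int)
    for j, p in enumerate(positions):
        data = per_pos[int(p)]
        n_events[j] = len(data)
        if len(data) < 3:
            continue  # undefined, reported as missing
        tau, mp, mc = map(np.array, zip(*data))
        if np.std(tau) > 0 and np.std(mp) > 0:
            r_prev[j] = stats.pearsonr(tau, mp)[0]
        if np.std(tau) > 0 and np.std(mc) > 0:
            r_cur[j] = stats.pearsonr(tau, mc)[0]
    crossover = None
    for j, p in enumerate(positions):
        if p > 0 and np.isfinite(r_prev[j]) and np.isfinite(r_cur[j]):
            if r_cur[j] > r_prev[j]:
                crossover = int(p)
                break
    return AdaptationCurve(
        positions=positions,
        r_previous=r_prev,
        r_current=r_cur,
        n_events=n_events,
        crossover_trial=crossover,
    )


# -- first-trial contrast ----------------------------------------------------


def first_trial_contrast(
    sessions_by_subject: list[list[SessionLog]],
    theta_low: float,
    theta_high: float,
    skip_session_head: int = 4,
):
    """Paired two-sided Wilcoxon signed-rank test of per-subject mean
    first-trial waiting times between two contexts.

    Zero differences are dropped (the classic signed-rank convention); if
    every pair is tied the test is degenerate and (nan, 1.0) is returned.
    """
    if len(sessions_by_subject) < 5:
        raise ValueError(
            f"need >= 5 subjects for the contrast, got {len(sessions_by_subject)}"
        )
    lo_means, hi_means = [], []
    for sessions in sessions_by_subject:
        lo, hi = [], []
        for session in sessions:
            blocks = _session_blocks(session, skip_session_head)
            for i in range(1, len(blocks)):  # first trial after a switch
                theta, trials = blocks[i]
                if not trials:
                    continue
                tau = trials[0].waiting_time_tau
                if np.isclose(theta, theta_low):
                    lo.append(tau)
                elif np.isclose(theta, theta_high):
                    hi.append(tau)
        lo_means.append(np.mean(lo) if lo else np.nan)
        hi_means.append(np.mean(hi) if hi else np.nan)
    lo_means = np.asarray(lo_means, dtype=float)
    hi_means = np.asarray(hi_means, dtype=float)
    ok = np.isfinite(lo_means) & np.isfinite(hi_means)
    d = hi_means[ok] - lo_means[ok]
    if len(d) < 5:
        raise ValueError("fewer than 5 subjects with data in both contexts")
    if np.allclose(d, 0.0):
        return {"statistic": float("nan"), "p_value": 1.0,
                "diffs": d, "low_means": lo_means, "high_means": hi_means}
    stat, p = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided")
    return {"statistic": float(stat), "p_value": float(p),
            "diffs": d, "low_means": lo_means, "high_means": hi_means}


# -- PCA ---------------------------------------------------------------------


def pca_hidden(
    hidden: np.ndarray,
    n_components: int | None = None,
    align_pc1: np.ndarray | None = None,
    align_pc2: np.ndarray | None = None,
) -> PCAReport:
    """PCA of the hidden-state stream (all steps, ITI included); data are
    mean-centered. Optional sign convention: PC1 is flipped to correlate
    positively with ``align_pc1`` (the decision variable), PC2 with
    ``align_pc2`` (the context estimate)."""
    h = np.asarray(hidden, dtype=float)
    if h.ndim != 2:
        raise ValueError("hidden must be samples x units")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(h)
    comps = pca.components_.copy()
    for k, ref in ((0, align_pc1), (1, align_pc2)):
        if ref is not None and scores.shape[1] > k:
            r = np.corrcoef(scores[:, k], np.asarray(ref, dtype=float))[0, 1]
            if np.isfinite(r) and r < 0:
                scores[:, k] *= -1.0
                comps[k] *= -1.0
    return PCAReport(
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_,
        scores=scores,
    )


# -- decoding ----------------------------------------------------------------


def sllr(s_hat: np.ndarray, clip: float = SLLR_CLIP) -> np.ndarray:
    """State log-likelihood ratio ln(s/(1-s)), clipped to a finite range
    (the estimate hits exactly 0 after every nogo)."""
    s = np.clip(np.asarray(s_hat, dtype=float), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        out = np.log(s) - np.log1p(-s)
    return np.clip(out, -clip, clip)


def _trial_mask(trace: dict) -> np.ndarray:
    phase = np.asarray(trace["phase"])
    return (phase == "unsafe") | (phase == "safe")


def _cv_splits(n: int, cv_scheme: str, seed: int = 0):
    if cv_scheme == "10fold":
        kf = KFold(n_splits=10, shuffle=True, random_state=seed)
        yield from kf.split(np.arange(n))
    elif cv_scheme == "half":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        half = n // 2
        yield perm[:half], perm[half:]
    else:
        raise ValueError(f"unknown cv_scheme {cv_scheme!r}")


def _held_out_r2(h, y, splits):
    scores = []
    for tr, te in splits:
        model = LinearRegression().fit(h[tr], y[tr])
        pred = model.predict(h[te])
        ss = np.sum((y[te] - np.mean(y[te])) ** 2)
        scores.append(1.0 - np.sum((y[te] - pred) ** 2) / ss)
    return np.array(scores)


def decode(trace: dict, target: str, cv_scheme: str = "10fold", seed: int = 0) -> DecodeReport:
    """Cross-validated linear decoding of a variable from hidden activity.

    ``trace`` must contain ``h`` (steps x units), ``phase`` (for excluding
    inter-trial intervals) and the target array. Targets:

    * ``s_true``   -- logistic regression, held-out accuracy
    * ``s_hat``    -- linear regression on the clipped SLLR, held-out R^2
    * ``theta_true`` / ``theta_hat`` -- linear regression, held-out R^2
    * ``delta``    -- s_hat and s_threshold are decoded in SLLR space,
                      mapped back through the logistic and differenced; R^2
                      against the true decision variable
    * any other key present in the trace -- linear regression, R^2
    """
    mask = _trial_mask(trace)
    h = np.asarray(trace["h"], dtype=float)[mask]
    n = len(h)

    def splits():
        return _cv_splits(n, cv_scheme, seed)

    if target == "s_true":
        y = np.asarray(trace["s_true"])[mask].astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate target: s_true is constant")
        scores = []
        for tr, te in splits():
            clf = LogisticRegression(max_iter=1000).fit(h[tr], y[tr])
            scores.append(float(np.mean(clf.predict(h[te]) == y[te])))
        scores = np.array(scores)
        return DecodeReport(target, "logistic", cv_scheme, float(scores.mean()), scores)

    if target == "delta":
        y_s = sllr(np.asarray(trace["s_hat"])[mask])
        y_thr = sllr(np.asarray(trace["s_threshold"])[mask])
        delta_true = np.asarray(trace["s_hat"])[mask] - np.asarray(
            trace["s_threshold"]
        )[mask]
        scores = []
        for tr, te in splits():
            m1 = LinearRegression().fit(h[tr], y_s[tr])
            m2 = LinearRegression().fit(h[tr], y_thr[tr])
            pred = _logistic(m1.predict(h[te])) - _logistic(m2.predict(h[te]))
            ss = np.sum((delta_true[te] - np.mean(delta_true[te])) ** 2)
            scores.append(1.0 - np.sum((delta_true[te] - pred) ** 2) / ss)
        scores = np.array(scores)
        return DecodeReport(target, "linear", cv_scheme, float(scores.mean()), scores)

    if target == "s_hat":
        y = sllr(np.asarray(trace["s_hat"])[mask])
    else:
        y = np.asarray(trace[target], dtype=float)[mask]
    if np.std(y) == 0:
        raise ValueError(f"degenerate target: {target} is constant")
    scores = _held_out_r2(h, y, splits())
    return DecodeReport(target, "linear", cv_scheme, float(scores.mean()), scores)


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def bayes_trace_along(trace: dict, model: BayesModel) -> dict:
    """Replay the ideal observer along a recorded trajectory (the cues and
    trial outcomes another agent produced), yielding per-step Bayesian
    variables (s_hat, theta_hat, s_threshold, delta) aligned to the trace."""
    agent = BayesAgent(model, record=True)
    xs = np.asarray(trace["x"], dtype=int)
    phases = np.asarray(trace["phase"])
    acts = np.asarray(trace["action"] if "action" in trace else trace["a"], dtype=int)
    rs = np.asarray(trace["r"], dtype=float)
    s_true = np.asarray(trace["s_true"], dtype=int)
    for t in range(len(xs)):
        agent.step(int(xs[t]), 0.0)
        ended = (acts[t] == 1 and phases[t] in ("unsafe", "safe")) or rs[t] != 0
        if ended:
            outcome = "rewarded" if s_true[t] == 1 else "premature"
            agent.notify_trial_end(outcome)
    out: dict[str, np.ndarray] = {}
    for k in ("s_hat", "theta_hat", "tau_star", "s_threshold", "delta"):
        out[k] = np.array([st[k] for st in agent.trace])
    return out


# -- planted-stimulus vector fields ------------------------------------------


def vector_field(
    agent_kind: str,
    n_per_theta: int = 500,
    thetas=(0.1, 0.3, 0.5, 0.7),
    planted_stimulus: np.ndarray | None = None,
    model: BayesModel | None = None,
    alpha: float = 0.9,
    net=None,
    projector=None,
    burn_in_trials: int = 8,
    task_config: TaskConfig | None = None,
    rng: np.random.Generator | None = None,
) -> VectorField:
    """Mean per-step displacement of an agent's internal coordinates while a
    fixed cue sequence is planted and the agent's actions are masked.

    For every context theta, the agent first runs ``burn_in_trials`` closed-
    loop trials (so its context estimate settles), then receives the planted
    stimulus with the action channel forced to zero. Axes: the Bayes agent
    projects onto (theta_hat, s_hat), the disjoint integrator onto
    (theta_tilde, s_tilde) and a network onto the first two rows of
    ``projector`` applied to its actor hidden state.
    """
    if planted_stimulus is None:
        planted_stimulus = PLANTED_STIMULUS
    stim = np.asarray(planted_stimulus, dtype=int)
    if rng is None:
        rng = np.random.default_rng(0)
    if model is None:
        model = BayesModel()
    if task_config is None:
        task_config = TaskConfig()
    thetas = np.asarray(thetas, dtype=float)
    L = len(stim)
    pos = np.zeros((len(thetas), L, 2))
    axis_names = {
        "bayes": ("theta_hat", "s_hat"),
        "integrator": ("theta_tilde", "s_tilde"),
        "network": ("pc1", "pc2"),
    }.get(agent_kind)
    if axis_names is None:
        raise ValueError(f"unsupported agent kind {agent_kind!r}")
    if agent_kind == "network" and (net is None or projector is None):
        raise ValueError("network vector field needs net and projector")

    for i, theta in enumerate(thetas):
        cfg = replace(
            task_config, theta_set=(float(theta),),
            block_length_range=(burn_in_trials, burn_in_trials), training=False,
        )
        acc = np.zeros((L, 2))
        for rep in range(n_per_theta):
            if agent_kind == "bayes":
                agent = BayesAgent(model, record=False)
            elif agent_kind == "integrator":
                agent = DisjointIntegratorAgent(alpha, model)
            else:
                agent = _NetProbe(net, projector)
            env = ChangeDetectionEnv(cfg, burn_in_trials, rng=rng, record_steps=False)
            env.run(agent, max_steps=2000)
            for k in range(L):
                agent.step(int(stim[k]), 0.0)  # action masked: never applied
                acc[k] += _project(agent, agent_kind)
        pos[i] = acc / n_per_theta
    disp = np.diff(pos, axis=1)
    return VectorField(
        stimulus=stim, thetas=thetas, positions=pos, displacements=disp,
        n_per_theta=n_per_theta, axis_names=axis_names,
    )


class _NetProbe:
    """Network wrapper that masks its own action input to zero."""

    def __init__(self, net, projector) -> None:
        self.net = net
        self.projector = np.asarray(projector)
        self.last_h = np.zeros(net.config.n_hidden)

    def step(self, x: int, prev_reward: float) -> int:
        u = [float(x), 0.0, 0.0]
        if self.net.config.variant == "readout_only_context":
            u.append(0.0)
        Q, V, cache = self.net.forward_step(np.asarray(u))
        self.last_h = cache[2]
        return 0


def _project(agent, kind: str) -> np.ndarray:
    if kind == "bayes":
        grid = agent.model.theta_grid
        return np.array(
            [float(agent.belief.context_marginal @ grid), float(agent.belief.p[1].sum())]
        )
    if kind == "integrator":
        return np.array([agent.state.theta_tilde, agent.state.s_tilde])
    h = agent.last_h
    proj = agent.projector[:2] @ h
    return np.asarray(proj, dtype=float)


# -- performance table -------------------------------------------------------


def performance_table(sessions: list[SessionLog], mean_iti: float | None = None):
    """Per-context reward rate (rewards per step, ITI included), mean and
    variance of the waiting time.

    If step records are present the true step counts are used; otherwise the
    inter-trial interval is charged at ``mean_iti`` steps per trial
    (defaults to the midpoint of the config's ITI range).
    """
    rows: dict[float, dict] = {}
    for session in sessions:
        if mean_iti is None:
            if session.config is not None:
                lo, hi = session.config.iti_range
                iti = 0.5 * (lo + hi)
            else:
                iti = 15.0
        else:
            iti = mean_iti
        for t in session.trials:
            row = rows.setdefault(
                t.theta, {"rewards": 0.0, "steps": 0.0, "taus": []}
            )
            row["rewards"] += 1.0 if t.outcome == "rewarded" else 0.0
            if t.steps:
                row["steps"] += len(t.steps)
            else:
                row["steps"] += t.duration_steps + iti
            if t.outcome in RESPONDED:
                row["taus"].append(t.waiting_time_tau)
    out = {}
    for theta in sorted(rows):
        row = rows[theta]
        taus = np.asarray(row["taus"], dtype=float)
        out[theta] = {
            "reward_rate": row["rewards"] / row["steps"] if row["steps"] else np.nan,
            "mean_tau": float(taus.mean()) if len(taus) else np.nan,
            "var_tau": float(taus.var()) if len(taus) else np.nan,
            "n_trials": len(row["taus"]),
        }
    return out
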