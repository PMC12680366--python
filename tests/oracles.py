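"""Independent oracles used by the test-suite.

These deliberately avoid the package's filtering/recursion code paths:
posteriors are computed by exhaustive enumeration of every latent
trajectory, and test statistics by direct enumeration of permutations.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_posterior(
    xs,
    prior: np.ndarray,
    lambda_: float,
    theta_grid: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Posterior P(s_T, theta_T | x_1..x_T) by brute-force enumeration of all
    latent (state, context) trajectories.

    The latent chain is (s_0, theta_0) ~ prior, then per step an independent
    state transition (unsafe -> safe w.p. lambda, safe absorbing) and context
    transition (stay w.p. 1-eps, else uniform over the other grid values),
    followed by the emission of x_t (safe: always go; unsafe: go w.p. theta).
    Trajectory probabilities are evaluated individually (the context-path
    product is vectorized over the full m^(T+1) path table) and summed.
    """
    xs = list(xs)
    T = len(xs)
    theta_grid = np.asarray(theta_grid, dtype=float)
    m = len(theta_grid)
    prior = np.asarray(prior, dtype=float)

    P_s = np.array([[1.0 - lambda_, 0.0], [lambda_, 1.0]])  # [new, old]
    if m == 1:
        P_t = np.ones((1, 1))
    else:
        P_t = np.full((m, m), epsilon / (m - 1))
        np.fill_diagonal(P_t, 1.0 - epsilon)

    # all context paths as digit tables: (m^(T+1), T+1)
    n_tp = m ** (T + 1)
    digits = (np.arange(n_tp)[:, None] // m ** np.arange(T + 1)) % m
    w_trans = np.ones(n_tp)
    for t in range(1, T + 1):
        w_trans = w_trans * P_t[digits[:, t], digits[:, t - 1]]
    theta_vals = theta_grid[digits]

    post = np.zeros((2, m))
    for s_path in itertools.product((0, 1), repeat=T + 1):
        w_s = 1.0
        for t in range(1, T + 1):
            w_s *= P_s[s_path[t], s_path[t - 1]]
        if w_s == 0.0:
            continue
        w = w_trans * prior[s_path[0], digits[:, 0]]
        feasible = True
        for t in range(1, T + 1):
            x = xs[t - 1]
            if s_path[t] == 1:
                if x == 0:
                    feasible = False
                    break
            else:
                th = theta_vals[:, t]
                w = w * (th if x == 1 else 1.0 - th)
        if not feasible:
            continue
        post[s_path[T]] += w_s * np.bincount(digits[:, T], weights=w, minlength=m)
    Z = post.sum()
    if Z <= 0.0:
        raise ValueError("observation sequence impossible under the prior")
    return post / Z


def scalar_hmm_filter(xs, lambda_: float, theta: float, p0: float = 0.0):
    """Known-context two-state forward filter in closed scalar form:
    p <- predict p + (1-p) lambda, then condition on the cue."""
    p = p0
    out = []
    for x in xs:
        pred = p + (1.0 - p) * lambda_
        if x == 1:
            p = pred / (pred + (1.0 - pred) * theta)
        else:
            num = 0.0
            den = (1.0 - pred) * (1.0 - theta)
            if den <= 0.0:
                raise ValueError("impossible observation")
            p = num / den if den > 0 else 0.0
        out.append(p)
    return np.array(out)


def exact_wilcoxon_p(diffs) -> tuple[float, float]:
    """Two-sided exact signed-rank p-value by enumerating all sign
    assignments; returns (W = min signed-rank sum, p)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0  # no ties assumed
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_obs = min(w_plus, w_minus)
    count = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        wp = float(sum(r for r, s in zip(ranks, signs) if s))
        wm = float(ranks.sum() - wp)
        if min(wp, wm) <= w_obs:
            count += 1
    return w_obs, count / total
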