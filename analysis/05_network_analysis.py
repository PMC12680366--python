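"""Neural analyses of the trained recurrent agents.

Loads the checkpoints written by 04_train_networks.py (training small ones
on the fly if absent), evaluates them with full hidden-state traces, and
asks whether the network implements joint Bayesian inference:

* per-context reward rates and waiting times per variant;
* PCA of the actor's short-term-memory stream (low-dimensional dynamics);
* cross-validated decoding of the true state, the Bayesian state estimate
  (in log-likelihood-ratio space), the context and the decision variable
  from hidden activity;
* the linear-integrator output fit: a reservoir's output is almost fully
  explained by a leaky integrator, a trained network's is not;
* planted-stimulus vector fields: a trailing nogo *raises* the Bayes (and
  network) context coordinate while it lowers a leaky integrator's.

Writes results/network_analysis.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from flexinfer.analysis import (
    bayes_trace_along,
    decode,
    pca_hidden,
    performance_table,
    vector_field,
)
from flexinfer.bayes import BayesModel
from flexinfer.integrators import fit_linear_output
from flexinfer.rnn import ActorCriticNet, NetConfig, RLHyperparams, evaluate, train
from flexinfer.task import TaskConfig

THETAS = (0.1, 0.3, 0.5, 0.7)


def get_net(netdir: Path, variant: str, seed: int, episodes: int):
    path = netdir / f"{variant}_0.npz"
    if path.exists():
        return ActorCriticNet.load(path)
    print(f"[{variant}] no checkpoint found, training {episodes} episodes ...")
    net, _ = train(
        NetConfig(n_hidden=50, variant=variant, seed=seed),
        RLHyperparams(n_episodes=episodes),
        TaskConfig(training=True, seed=seed),
    )
    return net


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--episodes", type=int, default=1_000)
    ap.add_argument("--eval-trials", type=int, default=600)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    netdir = args.out / "networks"

    report: dict = {}
    model = BayesModel(lambda_=0.1, epsilon=1e-3, m=10, T_iti=15.0)
    cfg = TaskConfig(theta_set=THETAS, block_length_range=(30, 60),
                     seed=args.seed + 5)

    traces = {}
    for variant, mode in (("trained", "argmax"), ("readout_only", "softmax"),
                          ("readout_only_context", "softmax")):
        net = get_net(netdir, variant, args.seed, args.episodes)
        log, trace = evaluate(net, cfg, args.eval_trials, mode=mode,
                              rng=np.random.default_rng(args.seed + 5))
        tab = performance_table([log])
        report[f"{variant}_performance"] = {
            str(th): {k: round(float(v), 5) for k, v in tab[th].items()}
            for th in tab
        }
        traces[variant] = trace

    # neural analyses on the fully trained network
    trace = traces["trained"]
    bayes_vars = bayes_trace_along(trace, model)
    trace.update(bayes_vars)
    trace["delta_true"] = bayes_vars["delta"]

    pca = pca_hidden(trace["h"], align_pc1=bayes_vars["delta"],
                     align_pc2=bayes_vars["theta_hat"])
    report["pca_explained_variance_top3"] = [
        round(float(v), 4) for v in pca.explained_variance_ratio[:3]
    ]

    decoding = {}
    for target in ("s_true", "s_hat", "theta_true", "theta_hat", "delta"):
        rep = decode(trace, target, cv_scheme="10fold", seed=args.seed)
        decoding[target] = round(float(rep.score), 4)
    report["decoding_10fold"] = decoding

    # network output Q vs the Bayesian decision variable
    mask = (np.asarray(trace["phase"]) == "unsafe") | (
        np.asarray(trace["phase"]) == "safe"
    )
    q, d = trace["Q"][mask], bayes_vars["delta"][mask]
    r = np.corrcoef(q, d)[0, 1]
    report["Q_vs_bayes_delta_r2"] = round(float(r * r), 4)

    # linear-integrator explanation of the output trace, per variant; the
    # trace is shifted by its minimum (absorbed by the positive baseline) so
    # the constrained model class is not ruled out by the sign of Q alone
    lin = {}
    for variant in ("trained", "readout_only"):
        tr = traces[variant]
        q = tr["Q"] - tr["Q"].min() + 0.1
        fit = fit_linear_output(q, tr["x"].astype(float),
                                fit_window=min(len(q), 100_000))
        lin[variant] = round(float(fit.r2_fit), 4)
    report["linear_output_r2"] = lin

    # planted-stimulus vector fields: context-coordinate move at the nogo
    vf_b = vector_field("bayes", n_per_theta=100, thetas=(0.3,), model=model,
                        rng=np.random.default_rng(args.seed))
    vf_i = vector_field("integrator", n_per_theta=100, thetas=(0.3,),
                        model=model, alpha=0.9,
                        rng=np.random.default_rng(args.seed))
    net = get_net(netdir, "trained", args.seed, args.episodes)
    vf_n = vector_field("network", n_per_theta=100, thetas=(0.3,), model=model,
                        net=net, projector=pca.components,
                        rng=np.random.default_rng(args.seed))
    report["nogo_context_displacement"] = {
        "bayes_theta_hat": round(float(vf_b.displacements[0, 8, 0]), 4),
        "integrator_theta_tilde": round(float(vf_i.displacements[0, 8, 0]), 4),
        "network_pc2": round(float(vf_n.displacements[0, 8, 1]), 4),
    }

    (args.out / "network_analysis.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
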