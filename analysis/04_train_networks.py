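"""Train the recurrent agents (scaled-down profile).

Trains one network per variant -- fully trained, readout-only (reservoir),
and readout-only with an explicit context input -- with the policy-gradient
recipe: 20-trial episodes at a per-episode context drawn from a 20-value
grid, advantage actor-critic losses, RMSprop, hidden state carried across
episodes. The default profile (1,000 episodes, 50 units) runs in minutes;
pass --episodes 10000 --hidden 100 --cohort 10 for the full-scale recipe.

Writes results/networks/<variant>_<i>.npz and results/learning_curves.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from flexinfer.rnn import NetConfig, RLHyperparams, train
from flexinfer.task import TaskConfig

VARIANTS = ("trained", "readout_only", "readout_only_context")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--episodes", type=int, default=1_000)
    ap.add_argument("--hidden", type=int, default=50)
    ap.add_argument("--cohort", type=int, default=1)
    args = ap.parse_args()
    netdir = args.out / "networks"
    netdir.mkdir(parents=True, exist_ok=True)

    hp = RLHyperparams(n_episodes=args.episodes)
    task = TaskConfig(training=True, seed=args.seed)
    curves = []
    for variant in VARIANTS:
        for i in range(args.cohort):
            cfg = NetConfig(n_hidden=args.hidden, variant=variant,
                            seed=args.seed + 1000 * i)
            net, curve = train(cfg, hp, task)
            net.save(netdir / f"{variant}_{i}.npz")
            tail = float(np.mean(curve["total_reward"][-100:]))
            head = float(np.mean(curve["total_reward"][:100]))
            print(f"{variant}[{i}]: mean episode reward {head:+.1f} -> {tail:+.1f}")
            for ep, tot in zip(curve["episode"], curve["total_reward"]):
                curves.append(
                    {"variant": variant, "net": i, "episode": ep,
                     "total_reward": tot}
                )
    pd.DataFrame(curves).to_csv(args.out / "learning_curves.csv", index=False)
    print(f"\nCheckpoints in {netdir}, learning curves in "
          f"{args.out / 'learning_curves.csv'}")


if __name__ == "__main__":
    main()
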