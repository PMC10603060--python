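"""Coarse grid calibration of the three-population solution.

The construction in ``popgate.populations.three_pop_statistics`` leaves
a handful of overlap magnitudes free.  This script evaluates task
accuracy of finite networks drawn from the construction over a coarse
parameter grid and prints the best settings, which are frozen as the
``ThreePopParams`` defaults.  Re-run after changing the construction:

    python scripts/calibrate_three_pop.py [--n 1500] [--trials 512]
"""

import argparse
import itertools

import numpy as np

from popgate.populations import ThreePopParams, build_three_pop_solution
from popgate.rnn import accuracy
from popgate.task import TaskParams


def evaluate(params: ThreePopParams, N: int, n_trials: int, seeds=(0, 1)) -> float:
    task = TaskParams()
    accs = []
    for s in seeds:
        net, _ = build_three_pop_solution(N=N, params=params, seed=s)
        accs.append(accuracy(net, task, n_trials=n_trials, seed=1000 + s)["overall"])
    return float(np.mean(accs))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=1500)
    ap.add_argument("--trials", type=int, default=512)
    ap.add_argument("--fine", action="store_true", help="refine around current defaults")
    args = ap.parse_args()

    if args.fine:
        d = ThreePopParams()
        grid = {
            "beta": [d.beta * f for f in (0.8, 1.0, 1.25)],
            "r_gate": [d.r_gate, d.r_gate + 0.5],
            "rho": [d.rho],
            "gamma_w": [d.gamma_w * f for f in (0.8, 1.0, 1.25)],
            "mu_stim": [d.mu_stim - 0.25, d.mu_stim, d.mu_stim + 0.25],
            "mu_sup": [d.mu_sup],
        }
    else:
        grid = {
            "beta": [4.0, 6.0, 8.0],
            "r_gate": [0.0, 1.0, 2.0],
            "rho": [0.3, 1.0],
            "gamma_w": [4.0, 7.0, 10.0],
            "mu_stim": [1.5, 2.0, 2.5],
            "mu_sup": [5.0],
        }

    keys = list(grid)
    results = []
    for combo in itertools.product(*grid.values()):
        params = ThreePopParams(**dict(zip(keys, combo)))
        acc = evaluate(params, args.n, args.trials)
        results.append((acc, dict(zip(keys, combo))))
    results.sort(key=lambda t: -t[0])
    for acc, combo in results[:10]:
        print(f"acc={acc:.4f}  {combo}")


if __name__ == "__main__":
    main()
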