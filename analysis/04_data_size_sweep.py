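#!/usr/bin/env python
"""Data-size sweep: retrain on 100/80/50/30% of the training patients.

The state space is fitted once on the full training split and held fixed;
every fraction is scored on identical bootstrap resamples of the test
patients, so the per-fraction reward distributions are directly
comparable.  Writes one distribution/summary/P-value/action file set per
fraction plus a combined summary.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from adrl.experiments import ExperimentConfig, run_test1, write_results


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--visits", type=pathlib.Path, default=pathlib.Path("results/states/prepared_visits.csv"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--reps", type=int, default=50)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/data_size_sweep"))
    args = parser.parse_args()

    visits = pd.read_csv(args.visits)
    config = ExperimentConfig(seed=args.seed, n_train_reps=args.reps)
    results = run_test1(visits, config)
    write_results(results, args.outdir, config)

    rows = []
    for fraction, result in sorted(results.items()):
        for policy, values in result.policy_values.items():
            rows.append({"train_fraction": fraction, "policy": policy, "mean_reward": float(np.mean(values))})
    combined = pd.DataFrame(rows).pivot(index="policy", columns="train_fraction", values="mean_reward")
    combined.to_csv(args.outdir / "mean_rewards_by_fraction.csv")
    print("mean step-WIS reward by training fraction:")
    print(combined.round(3).to_string())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
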