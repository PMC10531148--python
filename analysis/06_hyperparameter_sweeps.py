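#!/usr/bin/env python
"""Stratified and hyperparameter analyses: caseload split, learning rate,
state count.

Runs three sweeps on the prepared cohort: (1) JR/SR stratification by each
patient's mean MMSE relative to the grand mean, (2) Q-learning retrained at
learning rates 0.1-0.9, and (3) the state tree refitted at occupancy
thresholds 50/100/200.  Writes one result set per sweep level.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from adrl.experiments import ExperimentConfig, run_test3, run_test4, run_test5, write_results


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--visits", type=pathlib.Path, default=pathlib.Path("results/states/prepared_visits.csv"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--reps", type=int, default=10)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/hyperparameters"))
    args = parser.parse_args()

    visits = pd.read_csv(args.visits)
    config = ExperimentConfig(seed=args.seed, n_train_reps=args.reps)

    strata = run_test3(visits, config)
    write_results(strata, args.outdir / "jr_sr", config)
    print("caseload strata (mean Q-learning / clinician reward):")
    for name, result in strata.items():
        print(f"  {name}: q_learning {np.mean(result.policy_values['q_learning']):+.3f}  "
              f"clinician {np.mean(result.policy_values['clinician']):+.3f}")

    alphas = run_test4(visits, config)
    write_results(alphas, args.outdir / "learning_rate", config)
    print("\nQ-learning mean reward by learning rate:")
    print("  " + "  ".join(f"{a:.1f}:{np.mean(r.policy_values['q_learning']):+.3f}" for a, r in sorted(alphas.items())))

    occupancy = run_test5(visits, config)
    write_results(occupancy, args.outdir / "state_count", config)
    print("\nstate count and Q-learning mean reward by occupancy threshold:")
    for occ, result in sorted(occupancy.items()):
        print(f"  min_occupancy={occ}: {result.n_states} states, "
              f"reward {np.mean(result.policy_values['q_learning']):+.3f}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
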