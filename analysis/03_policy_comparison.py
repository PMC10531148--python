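#!/usr/bin/env python
"""Train the five policies on the whole-data cohort and compare them.

Runs the full pipeline once (state tree, logged MDP, policy iteration,
validation-selected Q-learning, clinician, zero, random), scores every
policy with step-WIS on bootstrap resamples of the test patients, and
writes the reward distributions, summary statistics, pairwise Welch t-test
P-values, the per-state recommended-action table and a box plot.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import adrl
from adrl.experiments import ExperimentConfig, compare_policies, policy_boxplot, run_pipeline, write_results


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--visits", type=pathlib.Path, default=pathlib.Path("results/states/prepared_visits.csv"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--reps", type=int, default=50)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/policy_comparison"))
    args = parser.parse_args()

    import pandas as pd

    visits = pd.read_csv(args.visits)
    config = ExperimentConfig(seed=args.seed, n_train_reps=args.reps)
    result = run_pipeline(visits, config, label="whole")
    write_results({"whole": result}, args.outdir, config)
    policy_boxplot(result, args.outdir / "whole_boxplot.png")

    report = compare_policies(result)
    print(f"states: {result.n_states}")
    print(report["summary"].to_string(index=False))
    print("\npairwise Welch t-test P-values:")
    print(report["pvalues"].round(4).to_string())
    print("\nper-state recommendations:")
    print(result.action_table.to_string())
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
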