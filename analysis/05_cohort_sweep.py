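#!/usr/bin/env python
"""Comorbidity-cohort sweep: the full policy comparison per analysis cohort.

Repeats the pipeline on the whole-data, AD, AD-hypertension, AD-depression
and AD-depression-hypertension cohorts and writes per-cohort reward
distributions and per-state recommended-action tables.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from adrl.experiments import ExperimentConfig, run_test2, write_results


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--visits", type=pathlib.Path, default=pathlib.Path("results/states/prepared_visits.csv"))
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--reps", type=int, default=50)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/cohort_sweep"))
    args = parser.parse_args()

    visits = pd.read_csv(args.visits)
    config = ExperimentConfig(seed=args.seed, n_train_reps=args.reps)
    results = run_test2(visits, config)
    write_results(results, args.outdir, config)

    for name, result in results.items():
        means = {p: float(np.mean(v)) for p, v in result.policy_values.items()}
        print(f"{name} ({result.n_states} states): " + "  ".join(f"{p}={m:+.3f}" for p, m in means.items()))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
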