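#!/usr/bin/env python
"""Simulate the synthetic longitudinal AD cohort and freeze its ground truth.

Writes the visit table (CSV with the standard header), the generator
configuration, the generating latent MDP and its exactly optimal treatment
policy, then prints cohort descriptives.  Every downstream analysis script
starts from these files.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np

import adrl
from adrl.actions import ACTION_NAMES


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-patients", type=int, default=1500)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/cohort"))
    args = parser.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    config = adrl.GeneratorConfig(n_patients=args.n_patients, seed=args.seed)
    mdp = adrl.default_true_mdp(config.n_latent_states)
    cohort = adrl.generate_cohort(config, mdp)

    adrl.write_cohort_csv(cohort, args.outdir / "visits.csv")
    config.to_yaml(args.outdir / "generator_config.yaml")
    mdp.to_yaml(args.outdir / "true_mdp.yaml")
    optimal = adrl.true_optimal_policy(mdp, gamma=0.3)
    with open(args.outdir / "true_optimal_policy.txt", "w") as fh:
        for s, a in enumerate(optimal.actions()):
            fh.write(f"latent_state_{s}\t{ACTION_NAMES[a]}\n")

    sizes = cohort.groupby("RID").size()
    print(f"patients: {cohort['RID'].nunique()}  visits: {len(cohort)}")
    print(f"visits per patient: mean {sizes.mean():.2f} (sd {sizes.std():.2f})")
    print(f"hypertension: {cohort.groupby('RID')['HYPERTENSION'].first().mean():.3f}  "
          f"depression: {cohort.groupby('RID')['DEPRESSION'].first().mean():.3f}")
    freq = cohort["TRUE_ACTION"].value_counts(normalize=True).sort_index()
    print("action frequencies:", {ACTION_NAMES[a]: round(f, 3) for a, f in freq.items()})
    print("true optimal policy:", [ACTION_NAMES[a] for a in optimal.actions()])
    print(f"wrote {args.outdir}/visits.csv")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
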