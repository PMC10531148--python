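#!/usr/bin/env python
"""Build the five analysis cohorts and derive the discrete state space.

Reads the simulated visit table, applies eligibility (>= 2 visits, complete
after carry-forward) and action coding, slices the five cohorts, then for
each cohort regresses MMSE on the candidate assessments, fits the state
tree, and writes the fitted rules plus a cohort summary table.
"""
import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

import adrl
from adrl.cohort_builder import COHORT_NAMES, build_cohort, prepare_visits
from adrl.state_space import fit_state_tree, load_published_rules, select_features


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--visits", type=pathlib.Path, default=pathlib.Path("results/cohort/visits.csv"))
    parser.add_argument("--min-occupancy", type=int, default=50)
    parser.add_argument("--outdir", type=pathlib.Path, default=pathlib.Path("results/states"))
    args = parser.parse_args()

    args.outdir.mkdir(parents=True, exist_ok=True)
    raw = adrl.read_cohort_csv(args.visits)
    prepared = prepare_visits(raw)
    prepared.to_csv(args.outdir / "prepared_visits.csv", index=False)

    selection = select_features(prepared)
    selection.table.to_csv(args.outdir / "feature_selection.csv", index=False)
    print("feature selection (OLS on MMSE):")
    print(selection.table.to_string(index=False))

    rows = []
    for name in COHORT_NAMES:
        subset = build_cohort(prepared, name)
        sel = select_features(subset)
        model = fit_state_tree(subset, sel.selected, min_occupancy=args.min_occupancy)
        model.save(args.outdir / f"states_{name}.yaml")
        rows.append(
            {
                "cohort": name,
                "patients": subset["RID"].nunique(),
                "visits": len(subset),
                "fitted_states": model.n_states,
                "published_states": load_published_rules(name).n_states,
            }
        )
    summary = pd.DataFrame(rows)
    summary.to_csv(args.outdir / "cohort_summary.csv", index=False)
    print()
    print(summary.to_string(index=False))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
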