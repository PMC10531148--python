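"""The experimental harness: five policies, five tests, bootstrap comparison.

Every test follows the same template on a prepared visit table: split the
patients 60/20/20 into train/validation/test, derive the discrete state
space and the logged MDP from the training split, train the two optimal-
policy solvers (Q-learning over repeated seeded runs, keeping the
repetition with the best validation step-WIS score), derive the clinician,
zero and random reference policies, and score all five on the test split
with step-WIS over bootstrap resamples of the test patients.  Bootstrap
resamples are shared across policies, so comparisons are paired.

All randomness descends from one master seed through labelled seed streams,
which makes every test byte-for-byte reproducible.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .actions import ACTION_NAMES, N_ACTIONS
from .cohort_builder import COHORT_NAMES, build_cohort
from .errors import ConfigurationError, DataError
from .ope import _estimate, _padded_log
from .policies import (
    TabularPolicy,
    behavior_policy,
    clinician_policy,
    greedy_policy,
    policy_iteration,
    q_learning,
    random_policy,
    zero_policy,
)
from .state_space import DEFAULT_FEATURES, fit_state_tree, select_features
from .trajectory_mdp import build_transitions, estimate_transition_model

logger = logging.getLogger(__name__)

POLICY_NAMES = ("policy_iteration", "q_learning", "clinician", "zero", "random")


def _subkey(text: str) -> int:
    """Stable 32-bit stream label for seed derivation."""
    return zlib.crc32(text.encode("utf8"))


@dataclass
class ExperimentConfig:
    """All tunables of the harness with the study defaults."""

    cohort: str = "WHOLE"
    split_fractions: tuple = (0.6, 0.2, 0.2)
    train_fractions: tuple = (1.0, 0.8, 0.5, 0.3)
    n_train_reps: int = 50
    n_bootstrap: int = 100
    gamma: float = 0.3
    alpha: float = 0.05
    n_passes: int = 50
    alpha_grid: tuple = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    min_occupancy_grid: tuple = (50, 100, 200)
    min_occupancy: int = 50
    max_depth: int = 6
    alpha_sig: float = 0.05
    features: tuple = tuple(DEFAULT_FEATURES)
    seed: int = 0

    def validate(self) -> None:
        if self.cohort not in COHORT_NAMES:
            raise ConfigurationError(f"cohort must be one of {COHORT_NAMES}")
        if len(self.split_fractions) != 3 or not np.isclose(sum(self.split_fractions), 1.0):
            raise ConfigurationError("split_fractions must be three values summing to 1")
        if any(f <= 0 for f in self.split_fractions):
            raise ConfigurationError("split_fractions must all be positive")
        if any(not 0 < f <= 1 for f in self.train_fractions):
            raise ConfigurationError("train_fractions must lie in (0, 1]")
        for name in ("n_train_reps", "n_bootstrap", "n_passes", "min_occupancy"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive count")
        if not 0.0 <= self.gamma < 1.0:
            raise ConfigurationError("gamma must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if any(not 0.0 < a < 1.0 for a in self.alpha_grid):
            raise ConfigurationError("alpha_grid entries must be in (0, 1)")
        if any(m < 1 for m in self.min_occupancy_grid):
            raise ConfigurationError("min_occupancy_grid entries must be positive")


@dataclass
class ExperimentResult:
    """Bootstrap reward distributions and per-state recommendations of one run."""

    label: str
    params: dict
    policy_values: dict  # policy name -> np.ndarray of n_bootstrap step-WIS values
    action_table: pd.DataFrame | None
    n_states: int
    state_labels: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, values in self.policy_values.items():
            rows.append(
                {
                    "policy": name,
                    "mean": float(np.mean(values)),
                    "median": float(np.median(values)),
                    "q1": float(np.percentile(values, 25)),
                    "q3": float(np.percentile(values, 75)),
                }
            )
        return pd.DataFrame(rows)

    def distributions(self) -> pd.DataFrame:
        return pd.DataFrame(self.policy_values)


def split_patients(patient_ids, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Disjoint patient-level train/validation/test split, deterministic per seed."""
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ConfigurationError("fractions must be three values summing to 1")
    if any(f <= 0 for f in fractions):
        raise ConfigurationError("all split fractions must be positive")
    ids = np.array(sorted(set(patient_ids)))
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_subkey("split"),)))
    perm = rng.permutation(len(ids))
    n = len(ids)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    train = ids[perm[:n_train]]
    val = ids[perm[n_train : n_train + n_val]]
    test = ids[perm[n_train + n_val :]]
    return train, val, test


def _bootstrap_values(
    policies: dict,
    behavior: TabularPolicy,
    test_trajs,
    gamma: float,
    n_bootstrap: int,
    rng: np.random.Generator,
) -> dict:
    """Paired bootstrap over test patients: every policy is scored on the
    identical resampled trajectory sets."""
    n = len(test_trajs)
    padded = {
        name: _padded_log(policy, behavior, test_trajs) for name, policy in policies.items()
    }
    out = {name: np.empty(n_bootstrap) for name in policies}
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        for name, (weights, rewards) in padded.items():
            out[name][b] = _estimate(weights[idx], rewards[idx], gamma)[0]
    return out


def run_pipeline(
    visits: pd.DataFrame,
    config: ExperimentConfig,
    *,
    label: str = "run",
    train_fraction: float = 1.0,
    min_occupancy: int | None = None,
    alpha: float | None = None,
    include=POLICY_NAMES,
    state_model=None,
    bootstrap_label: str | None = None,
) -> ExperimentResult:
    """One full train/evaluate cycle on a prepared (action-coded, complete)
    visit table; the unit every test composes.

    ``state_model`` optionally injects a prefitted state space (used by the
    data-size sweep, which holds the state definition fixed while the
    training data shrink).  ``bootstrap_label`` names the bootstrap seed
    stream; runs sharing it are scored on identical test resamples, making
    cross-run comparisons paired.
    """
    config.validate()
    if "ACTION" not in visits.columns:
        raise DataError("visits must carry the derived ACTION column (see cohort_builder)")
    min_occ = config.min_occupancy if min_occupancy is None else min_occupancy
    alpha = config.alpha if alpha is None else alpha

    train_ids, val_ids, test_ids = split_patients(
        visits["RID"], config.split_fractions, seed=config.seed
    )
    if train_fraction < 1.0:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(_subkey(label), _subkey("subsample"))))
        n_keep = max(2, int(round(train_fraction * len(train_ids))))
        train_ids = np.sort(rng.choice(train_ids, size=n_keep, replace=False))
    if len(train_ids) < 2:
        raise DataError(f"train fraction {train_fraction} leaves fewer than 2 patients")

    train = visits[visits["RID"].isin(train_ids)]
    val = visits[visits["RID"].isin(val_ids)]
    test = visits[visits["RID"].isin(test_ids)]

    if state_model is None:
        candidates = [f for f in config.features if f in visits.columns]
        selection = select_features(train, candidates, config.alpha_sig)
        features = selection.selected or candidates
        model = fit_state_tree(train, features, min_occupancy=min_occ, max_depth=config.max_depth)
    else:
        model = state_model
        features = model.features
    n_states = model.n_states

    trajs = {
        name: build_transitions(model.assign_frame(part), gamma=config.gamma)
        for name, part in (("train", train), ("val", val), ("test", test))
    }
    if not trajs["train"] or not trajs["test"]:
        raise DataError("train or test split produced no usable trajectories")

    mdp_hat = estimate_transition_model(trajs["train"], n_states)
    behavior_train = behavior_policy(trajs["train"], n_states)

    policies: dict[str, TabularPolicy] = {}
    if "policy_iteration" in include:
        policies["policy_iteration"] = policy_iteration(mdp_hat, config.gamma)
    if "q_learning" in include:
        best_pol, best_score = None, -np.inf
        behavior_val = behavior_policy(trajs["val"], n_states) if trajs["val"] else None
        for rep in range(config.n_train_reps):
            rep_seed = np.random.SeedSequence(
                config.seed, spawn_key=(_subkey(label), _subkey("qlearn"), rep)
            )
            qt = q_learning(
                trajs["train"],
                gamma=config.gamma,
                alpha=alpha,
                n_passes=config.n_passes,
                seed=rep_seed,
                n_states=n_states,
            )
            pol = greedy_policy(qt)
            if behavior_val is None:  # no validation data: keep the first repetition
                best_pol = pol
                break
            weights, rewards = _padded_log(pol, behavior_val, trajs["val"])
            score = _estimate(weights, rewards, config.gamma)[0]
            if score > best_score:
                best_pol, best_score = pol, score
        policies["q_learning"] = best_pol
    if "clinician" in include:
        policies["clinician"] = clinician_policy(mdp_hat, behavior_train, config.gamma)
    if "zero" in include:
        policies["zero"] = zero_policy(n_states)
    if "random" in include:
        policies["random"] = random_policy(n_states)

    behavior_test = behavior_policy(trajs["test"], n_states)
    boot_rng = np.random.default_rng(
        np.random.SeedSequence(
            config.seed,
            spawn_key=(_subkey(bootstrap_label or label), _subkey("bootstrap")),
        )
    )
    values = _bootstrap_values(
        policies, behavior_test, trajs["test"], config.gamma, config.n_bootstrap, boot_rng
    )

    action_table = pd.DataFrame(
        {name: [ACTION_NAMES[a] for a in pol.actions()] for name, pol in policies.items()},
        index=[s.label for s in model.states],
    )
    action_table.index.name = "state"

    return ExperimentResult(
        label=label,
        params={
            "train_fraction": train_fraction,
            "min_occupancy": min_occ,
            "alpha": alpha,
            "gamma": config.gamma,
            "seed": config.seed,
            "n_train_patients": int(len(train_ids)),
            "features": list(features),
        },
        policy_values=values,
        action_table=action_table,
        n_states=n_states,
        state_labels=[s.label for s in model.states],
    )


def run_test1(visits: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Data-size sweep: rerun the pipeline on shrinking fractions of the
    training patients; returns {train_fraction: ExperimentResult}.

    The state space is fitted once on the full training split and held fixed
    across fractions (the sweep varies the data feeding the solvers, not the
    state definition), and all fractions share one bootstrap stream so the
    per-fraction reward distributions are paired.
    """
    config.validate()
    if "ACTION" not in visits.columns:
        raise DataError("visits must carry the derived ACTION column (see cohort_builder)")
    train_ids, _, _ = split_patients(visits["RID"], config.split_fractions, seed=config.seed)
    train = visits[visits["RID"].isin(train_ids)]
    candidates = [f for f in config.features if f in visits.columns]
    features = select_features(train, candidates, config.alpha_sig).selected or candidates
    state_model = fit_state_tree(
        train, features, min_occupancy=config.min_occupancy, max_depth=config.max_depth
    )
    results: dict[float, ExperimentResult] = {}
    for fraction in config.train_fractions:
        try:
            results[fraction] = run_pipeline(
                visits,
                config,
                label=f"test1:{fraction}",
                train_fraction=fraction,
                state_model=state_model,
                bootstrap_label="test1",
            )
        except DataError as exc:
            logger.warning("run_test1: fraction %s skipped (%s)", fraction, exc)
    return results


def run_test2(visits: pd.DataFrame, config: ExperimentConfig, cohorts=COHORT_NAMES) -> dict:
    """Comorbidity-cohort sweep: the full comparison per analysis cohort."""
    config.validate()
    results: dict[str, ExperimentResult] = {}
    for name in cohorts:
        subset = build_cohort(visits, name)
        if subset.empty or subset["RID"].nunique() < 5:
            logger.warning("run_test2: cohort %s empty or too small; skipped", name)
            continue
        results[name] = run_pipeline(subset, config, label=f"test2:{name}")
    return results


def jr_sr_split(visits: pd.DataFrame) -> pd.Series:
    """Patient stratum labels: JR if the patient's mean MMSE over all visits
    is below the grand mean of per-patient means, SR otherwise."""
    patient_means = visits.groupby("RID")["MMSE"].mean()
    grand_mean = patient_means.mean()
    return pd.Series(
        np.where(patient_means < grand_mean, "JR", "SR"), index=patient_means.index
    )


def run_test3(visits: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Caseload stratification: the comparison within the JR stratum, the SR
    stratum, and the combined cohort."""
    config.validate()
    strata = jr_sr_split(visits)
    results: dict[str, ExperimentResult] = {}
    for name in ("JR", "SR"):
        ids = strata[strata == name].index
        subset = visits[visits["RID"].isin(ids)]
        if subset["RID"].nunique() < 5:
            logger.warning("run_test3: stratum %s too small; skipped", name)
            continue
        results[name] = run_pipeline(subset, config, label=f"test3:{name}")
    results["COMBINED"] = run_pipeline(visits, config, label="test3:COMBINED")
    return results


def run_test4(visits: pd.DataFrame, config: ExperimentConfig) -> dict:
    """Learning-rate sweep: Q-learning retrained at each alpha on the fixed split."""
    config.validate()
    results: dict[float, ExperimentResult] = {}
    for alpha in config.alpha_grid:
        results[alpha] = run_pipeline(
            visits,
            config,
            label=f"test4:{alpha}",
            alpha=alpha,
            include=("q_learning", "clinician"),
        )
    return results


def run_test5(visits: pd.DataFrame, config: ExperimentConfig) -> dict:
    """State-count sweep: refit the state tree per occupancy threshold and rerun."""
    config.validate()
    results: dict[int, ExperimentResult] = {}
    for min_occ in config.min_occupancy_grid:
        results[min_occ] = run_pipeline(
            visits,
            config,
            label=f"test5:{min_occ}",
            min_occupancy=min_occ,
            include=("q_learning", "clinician"),
        )
    return results


def compare_policies(result: ExperimentResult, equal_var: bool = False) -> dict:
    """Summary statistics and pairwise t-test P-values (Welch by default)."""
    names = list(result.policy_values)
    if len(names) < 2:
        raise DataError("compare_policies needs at least 2 policy distributions")
    lengths = {len(v) for v in result.policy_values.values()}
    if len(lengths) != 1:
        raise DataError("policy distributions have unequal lengths")
    pvals = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                x = result.policy_values[a]
                y = result.policy_values[b]
                if np.array_equal(x, y):
                    p = 1.0
                else:
                    p = float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)
                pvals.iloc[i, j] = pvals.iloc[j, i] = p
    pvals.index.name = "policy"
    return {"summary": result.summary(), "pvalues": pvals}


def policy_boxplot(result: ExperimentResult, path=None):
    """Box plot of the per-policy bootstrap reward distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(result.policy_values)
    fig, ax = plt.subplots(figsize=(1.6 * len(names) + 1, 4))
    ax.boxplot([result.policy_values[n] for n in names], tick_labels=names)
    ax.set_ylabel("step-WIS reward (discounted MMSE points)")
    ax.set_title(result.label)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def write_results(results: dict, outdir, config: ExperimentConfig | None = None) -> None:
    """Write distributions/summary/P-value/action tables as CSV, one prefix
    per run; output is byte-identical across repeated runs with one seed."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in sorted(results, key=str):
        result = results[key]
        prefix = str(key).replace("/", "_")
        result.distributions().to_csv(outdir / f"{prefix}_distributions.csv", index=False)
        report = compare_policies(result) if len(result.policy_values) > 1 else None
        result.summary().to_csv(outdir / f"{prefix}_summary.csv", index=False)
        if report is not None:
            report["pvalues"].to_csv(outdir / f"{prefix}_pvalues.csv")
        if result.action_table is not None:
            result.action_table.to_csv(outdir / f"{prefix}_actions.csv")
    if config is not None:
        import yaml

        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
                fh,
                sort_keys=False,
            )


def with_overrides(config: ExperimentConfig, **overrides) -> ExperimentConfig:
    return replace(config, **overrides)
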