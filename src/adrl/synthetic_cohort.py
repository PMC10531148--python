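"""Synthetic longitudinal AD cohort with a known ground-truth treatment MDP.

Real AD registry data (longitudinal visit tables with cognitive assessments
and medication logs) are access-controlled, so every downstream stage of
the pipeline is exercised on cohorts simulated from an explicit latent
Markov decision process.  Each patient carries a hidden severity state; at
each six-monthly visit the assessments are emitted as truncated, rounded
Gaussians around that state's characteristic means, a clinician-like
*behavior policy* (softmax over state-dependent logits, full support)
prescribes one of the six medication classes, and the latent state evolves
according to a treatment-dependent transition tensor.  Because the
generating MDP is known, the exactly optimal prescription policy is known
by construction and serves as the recovery target for end-to-end tests.

Randomness is hierarchical: one global seed plus the patient index
deterministically seeds each patient's stream, so patient k's record is
identical whether 100 or 10 000 patients are generated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import actions as act
from .errors import ConfigurationError, DomainError
from .policies import TabularPolicy, policy_iteration
from .trajectory_mdp import TransitionModel

ASSESSMENTS = ["MMSE", "ADAS13", "RAVLT_IMMEDIATE", "RAVLT_LEARNING", "CDRSB", "MOCA", "FDG"]

SCORE_RANGES = {
    "MMSE": (0.0, 30.0),
    "ADAS13": (0.0, 85.0),
    "RAVLT_IMMEDIATE": (0.0, 75.0),
    "RAVLT_LEARNING": (-5.0, 14.0),
    "CDRSB": (0.0, 18.0),
    "MOCA": (0.0, 30.0),
    "FDG": (0.3, 2.0),
}

# instrument granularity: integer scores for the cognitive batteries,
# half-point steps for CDRSB, continuous for the PET ratio
SCORE_GRANULARITY = {
    "MMSE": 1.0,
    "ADAS13": 1.0,
    "RAVLT_IMMEDIATE": 1.0,
    "RAVLT_LEARNING": 1.0,
    "CDRSB": 0.5,
    "MOCA": 1.0,
    "FDG": None,
}

DEFAULT_NOISE_SD = {
    "MMSE": 1.0,
    "ADAS13": 2.0,
    "RAVLT_IMMEDIATE": 3.0,
    "RAVLT_LEARNING": 1.0,
    "CDRSB": 0.5,
    "MOCA": 1.0,
    "FDG": 0.05,
}

VISIT_COLUMNS = [
    "RID",
    "VISCODE",
    "MONTH",
    "AGE",
    "MMSE",
    "ADAS13",
    "RAVLT_IMMEDIATE",
    "RAVLT_LEARNING",
    "CDRSB",
    "MOCA",
    "FDG",
    "DX",
    "HYPERTENSION",
    "DEPRESSION",
    "MEDICATIONS",
]


@dataclass
class GeneratorConfig:
    """Cohort-level knobs; defaults emulate a mid-sized AD registry."""

    n_patients: int = 1500
    visit_interval_months: float = 6.0
    visits_min: int = 2
    visits_max: int = 15
    hypertension_prevalence: float = 0.40
    depression_prevalence: float = 0.30
    n_latent_states: int = 5
    missing_rate: float = 0.05
    score_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    age_range: tuple = (55.0, 90.0)
    behavior_temperature: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.visit_interval_months <= 0:
            raise ConfigurationError("visit_interval_months must be positive")
        if self.visits_min < 2:
            raise ConfigurationError("visits_min must be >= 2")
        if self.visits_max < self.visits_min:
            raise ConfigurationError("visits_max must be >= visits_min")
        for name in ("hypertension_prevalence", "depression_prevalence", "missing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.n_latent_states < 2:
            raise ConfigurationError("n_latent_states must be >= 2")
        for name, sd in self.score_noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"score_noise_sd[{name!r}] must be nonnegative")
        if self.behavior_temperature <= 0:
            raise ConfigurationError("behavior_temperature must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must be increasing")

    def to_yaml(self, path) -> None:
        payload = {
            **{k: getattr(self, k) for k in (
                "n_patients", "visit_interval_months", "visits_min", "visits_max",
                "hypertension_prevalence", "depression_prevalence", "n_latent_states",
                "missing_rate", "behavior_temperature", "seed")},
            "score_noise_sd": dict(self.score_noise_sd),
            "age_range": list(self.age_range),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["age_range"] = tuple(payload.get("age_range", (55.0, 90.0)))
        return cls(**payload)


@dataclass
class TrueMDP:
    """The generating latent MDP: dynamics, expected MMSE change, emissions."""

    transition: np.ndarray  # (S, A, S)
    mean_mmse_change: np.ndarray  # (S, A), MMSE points per interval
    emission_means: dict  # assessment name -> (S,) means
    behavior_logits: np.ndarray  # (S, A) clinician-like prescribing propensities
    initial_distribution: np.ndarray  # (S,)
    dx_labels: list  # per-latent-state diagnosis label

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def n_actions(self) -> int:
        return self.transition.shape[1]

    def validate(self) -> None:
        S, A = self.n_states, self.n_actions
        if self.transition.shape != (S, A, S):
            raise ConfigurationError("transition tensor must be (S, A, S)")
        if np.any(self.transition < 0):
            raise ConfigurationError("transition probabilities must be nonnegative")
        if not np.allclose(self.transition.sum(axis=2), 1.0, atol=1e-12):
            raise ConfigurationError("transition rows must sum to 1")
        if self.mean_mmse_change.shape != (S, A):
            raise ConfigurationError("mean_mmse_change must be (S, A)")
        for name, means in self.emission_means.items():
            lo, hi = SCORE_RANGES[name]
            if np.any(np.asarray(means) < lo) or np.any(np.asarray(means) > hi):
                raise ConfigurationError(f"emission means for {name} outside [{lo}, {hi}]")
        if not np.isclose(self.initial_distribution.sum(), 1.0):
            raise ConfigurationError("initial_distribution must sum to 1")

    def behavior_probs(self, temperature: float = 1.0) -> np.ndarray:
        z = self.behavior_logits / temperature
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def to_yaml(self, path) -> None:
        payload = {
            "transition": self.transition.tolist(),
            "mean_mmse_change": self.mean_mmse_change.tolist(),
            "emission_means": {k: np.asarray(v).tolist() for k, v in self.emission_means.items()},
            "behavior_logits": self.behavior_logits.tolist(),
            "initial_distribution": self.initial_distribution.tolist(),
            "dx_labels": list(self.dx_labels),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TrueMDP":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        return cls(
            transition=np.array(p["transition"], dtype=float),
            mean_mmse_change=np.array(p["mean_mmse_change"], dtype=float),
            emission_means={k: np.array(v, dtype=float) for k, v in p["emission_means"].items()},
            behavior_logits=np.array(p["behavior_logits"], dtype=float),
            initial_distribution=np.array(p["initial_distribution"], dtype=float),
            dx_labels=list(p["dx_labels"]),
        )


def default_true_mdp(n_latent_states: int = 5) -> TrueMDP:
    """The package's reference disease-progression MDP.

    Latent states are ordered by severity with well-separated assessment
    profiles.  Each state has one clearly best medication class (ChEIs early,
    memantine or the combination late): under it the patient mostly holds
    steady with a real chance of improving a stage, while under any other
    class — and especially under no treatment — decline to the next stage
    dominates.  Expected MMSE change per (state, action) is derived from the
    transition tensor and the MMSE emission profile, so observed rewards are
    consistent with the latent dynamics by construction.
    """
    S = int(n_latent_states)
    if S < 2:
        raise ConfigurationError("n_latent_states must be >= 2")
    A = act.N_ACTIONS
    sev = np.linspace(0.0, 1.0, S)  # 0 = mildest

    emission_means = {
        "MMSE": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [29, 25, 20, 14, 6]),
        "ADAS13": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [8, 15, 24, 38, 52]),
        "RAVLT_IMMEDIATE": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [55, 42, 30, 18, 8]),
        "RAVLT_LEARNING": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [7, 5, 4, 2, 1]),
        "CDRSB": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [0.5, 2, 5, 9, 14]),
        "MOCA": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [28, 24, 18, 12, 5]),
        "FDG": np.interp(sev, [0, 0.25, 0.5, 0.75, 1], [1.35, 1.2, 1.05, 0.9, 0.75]),
    }

    # best medication class per severity stage: ChEIs while mild, the
    # combination or memantine once moderate/severe
    best = np.array(
        [act.CHEI if f < 0.35 else (act.MEMANTINE if 0.55 < f < 0.8 else act.CHEI_MEMANTINE) for f in sev]
    )

    transition = np.zeros((S, A, S))
    for s in range(S):
        for a in range(A):
            if a == best[s]:
                up, stay, down = (0.30, 0.70, 0.0) if s == S - 1 else (0.10, 0.85, 0.05)
            elif a == act.NO_DRUGS:
                up, stay, down = 0.01, 0.29, 0.70
            else:
                up, stay, down = 0.04, 0.41, 0.55
            row = np.zeros(S)
            row[max(s - 1, 0)] += up
            row[s] += stay
            row[min(s + 1, S - 1)] += down
            transition[s, a] = row / row.sum()

    mmse = emission_means["MMSE"]
    mean_mmse_change = np.einsum("sat,t->sa", transition, mmse) - mmse[:, None]

    # clinician-like prescribing: watchful waiting and supplements while
    # mild, AD-specific drugs with growing probability as severity rises;
    # every class keeps positive probability at every stage
    mild = np.array([1.2, -0.3, -1.2, -1.8, 0.2, 0.9])
    severe = np.array([-0.6, 0.5, 0.8, 1.0, 0.0, 0.2])
    behavior_logits = mild[None, :] + sev[:, None] * (severe - mild)[None, :]

    initial = np.linspace(1.3, 0.7, S)
    initial = initial / initial.sum()

    dx_labels = ["CN" if m >= 27 else ("MCI" if m >= 18 else "AD") for m in mmse]

    mdp = TrueMDP(
        transition=transition,
        mean_mmse_change=mean_mmse_change,
        emission_means=emission_means,
        behavior_logits=behavior_logits,
        initial_distribution=initial,
        dx_labels=dx_labels,
    )
    mdp.validate()
    return mdp


def true_optimal_policy(mdp: TrueMDP, gamma: float) -> TabularPolicy:
    """Exactly optimal deterministic policy of the latent MDP (reward =
    expected MMSE change), via exact policy iteration."""
    if not 0.0 <= gamma < 1.0:
        raise DomainError(f"gamma must be in [0, 1), got {gamma}")
    model = TransitionModel.from_arrays(mdp.transition, mdp.mean_mmse_change)
    return policy_iteration(model, gamma)


# -- cohort generation ----------------------------------------------------

_MED_RENDER = {
    act.NO_DRUGS: (),
    act.CHEI: act.DEFAULT_DRUG_DICTIONARY["CHEI"][:3],  # generic names only
    act.MEMANTINE: ("memantine",),
    act.CHEI_MEMANTINE: None,  # handled below
    act.ANTIHTN: act.DEFAULT_DRUG_DICTIONARY["ANTIHTN"][:5],
    act.SUPPLEMENT: act.SUPPLEMENT_EXAMPLES,
}


def _render_medications(action: int, rng: np.random.Generator) -> str:
    if action == act.NO_DRUGS:
        return ""
    if action == act.CHEI_MEMANTINE:
        chei = _MED_RENDER[act.CHEI][rng.integers(len(_MED_RENDER[act.CHEI]))]
        return f"{chei}|memantine"
    options = _MED_RENDER[action]
    return options[rng.integers(len(options))]


def _viscode(month: float) -> str:
    return "bl" if month == 0 else f"m{int(round(month)):02d}"


def generate_cohort(config: GeneratorConfig, mdp: TrueMDP | None = None) -> pd.DataFrame:
    """Simulate the visit table; returns a DataFrame in the standard column
    order plus two hidden ground-truth columns (LATENT_STATE, TRUE_ACTION)
    that the CSV writer drops.

    MMSE is never missing at the baseline visit; every other score cell is
    masked at ``missing_rate``.
    """
    config.validate()
    if mdp is None:
        mdp = default_true_mdp(config.n_latent_states)
    mdp.validate()
    if mdp.n_states != config.n_latent_states:
        raise ConfigurationError(
            f"n_latent_states ({config.n_latent_states}) does not match the MDP ({mdp.n_states})"
        )
    behavior = mdp.behavior_probs(config.behavior_temperature)
    rows = []
    for i in range(config.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        n_visits = int(rng.integers(config.visits_min, config.visits_max + 1))
        lo, hi = config.age_range
        age0 = float(rng.uniform(lo, hi - 2.0))
        htn = bool(rng.random() < config.hypertension_prevalence)
        dep = bool(rng.random() < config.depression_prevalence)
        latent = int(rng.choice(mdp.n_states, p=mdp.initial_distribution))
        for t in range(n_visits):
            month = t * config.visit_interval_months
            scores = {}
            for name in ASSESSMENTS:
                mean = mdp.emission_means[name][latent]
                sd = config.score_noise_sd.get(name, 0.0)
                value = float(rng.normal(mean, sd)) if sd > 0 else float(mean)
                rlo, rhi = SCORE_RANGES[name]
                value = min(max(value, rlo), rhi)
                step = SCORE_GRANULARITY[name]
                if step is not None:
                    value = round(value / step) * step
                missing = rng.random() < config.missing_rate
                if name == "MMSE" and t == 0:
                    missing = False
                scores[name] = np.nan if missing else value
            action = int(rng.choice(mdp.n_actions, p=behavior[latent]))
            rows.append(
                {
                    "RID": i + 1,
                    "VISCODE": _viscode(month),
                    "MONTH": month,
                    "AGE": round(age0 + month / 12.0, 1),
                    **scores,
                    "DX": mdp.dx_labels[latent],
                    "HYPERTENSION": int(htn),
                    "DEPRESSION": int(dep),
                    "MEDICATIONS": _render_medications(action, rng),
                    "LATENT_STATE": latent,
                    "TRUE_ACTION": action,
                }
            )
            latent = int(rng.choice(mdp.n_states, p=mdp.transition[latent, action]))
    return pd.DataFrame(rows, columns=VISIT_COLUMNS + ["LATENT_STATE", "TRUE_ACTION"])


def write_cohort_csv(visits: pd.DataFrame, path) -> None:
    """Write the fixed-header comma-separated visit table (ground-truth
    columns are dropped; medication lists are pipe-separated in-cell)."""
    visits[VISIT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    df["MEDICATIONS"] = df["MEDICATIONS"].fillna("")
    return df


def subset_mdp(mdp: TrueMDP, **overrides) -> TrueMDP:
    """Copy of the MDP with selected fields replaced (testing convenience)."""
    return replace(mdp, **overrides)
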