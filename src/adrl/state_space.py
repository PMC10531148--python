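"""Discrete disease states from a regression tree over assessment scores.

The state space is built in two steps: ordinary least squares picks the
assessment features that significantly predict MMSE, then a binary
axis-aligned regression tree on those features predicts MMSE and its leaves
become the discrete states.  Leaves are numbered in depth-first order and a
minimum-occupancy threshold (default 50 training visits) prunes rare states;
visits falling into a pruned region are "unassigned" and the downstream MDP
drops transitions that touch them.

Interval convention: splits produce left-open, right-closed intervals
``(a, b]`` — a visit sitting exactly on a split threshold belongs to the
lower leaf.  A published rule set with the same convention ships as a
package fixture and can be loaded per cohort in place of refitting.
"""
from __future__ import annotations

import importlib.resources
import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml
from sklearn.tree import DecisionTreeRegressor

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

UNASSIGNED = -1

DEFAULT_MIN_OCCUPANCY = 50
DEFAULT_MAX_DEPTH = 6
DEFAULT_ALPHA_SIG = 0.05

#: candidate predictors of MMSE used throughout the pipeline
DEFAULT_FEATURES = [
    "ADAS13",
    "RAVLT_IMMEDIATE",
    "RAVLT_LEARNING",
    "AGE",
    "CDRSB",
    "MOCA",
    "FDG",
]

COHORT_NAMES = ("WHOLE", "AD", "AD_HTN", "AD_DEP", "AD_DEP_HTN")


@dataclass(frozen=True)
class Rule:
    """One axis-aligned constraint: value of ``feature`` lies in the interval."""

    feature: str
    lo: float = -math.inf
    lo_closed: bool = False
    hi: float = math.inf
    hi_closed: bool = True

    def contains(self, value: float) -> bool:
        if value > self.lo or (self.lo_closed and value == self.lo):
            return value < self.hi or (self.hi_closed and value == self.hi)
        return False

    def contains_array(self, values: np.ndarray) -> np.ndarray:
        lower = values >= self.lo if self.lo_closed else values > self.lo
        upper = values <= self.hi if self.hi_closed else values < self.hi
        return lower & upper

    def __str__(self) -> str:
        left = "[" if self.lo_closed else "("
        right = "]" if self.hi_closed else ")"
        lo = "" if math.isinf(self.lo) else f"{self.lo:g}"
        hi = "" if math.isinf(self.hi) else f"{self.hi:g}"
        return f"{self.feature} {left}{lo},{hi}{right}"


@dataclass
class LeafState:
    label: str
    rules: list[Rule]
    occupancy: int = 0
    predicted_mmse: float | None = None
    pruned: bool = False


@dataclass
class StateSpaceModel:
    """Ordered leaf states of the fitted (or published) decision tree."""

    states: list[LeafState]
    features: list[str]
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY
    anomalies: list[str] = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_active_states(self) -> int:
        return sum(not s.pruned for s in self.states)

    def occupancy(self) -> np.ndarray:
        return np.array([s.occupancy for s in self.states])

    # -- assignment -----------------------------------------------------

    def assign(self, visit, check_unique: bool = False) -> int:
        """State index for one visit (mapping or Series); UNASSIGNED if the
        visit falls in no retained leaf region."""
        matches = []
        for idx, leaf in enumerate(self.states):
            ok = True
            for rule in leaf.rules:
                value = visit.get(rule.feature)
                if value is None or (isinstance(value, float) and math.isnan(value)):
                    raise DataError(f"visit is missing required feature {rule.feature!r}")
                if not rule.contains(float(value)):
                    ok = False
                    break
            if ok:
                if not check_unique:
                    return UNASSIGNED if leaf.pruned else idx
                matches.append(idx)
        if not matches:
            return UNASSIGNED
        if len(matches) > 1:
            raise DataError(f"visit matched {len(matches)} leaves: {matches}")
        idx = matches[0]
        return UNASSIGNED if self.states[idx].pruned else idx

    def assign_frame(self, visits: pd.DataFrame, column: str = "STATE") -> pd.DataFrame:
        """Vectorized assignment; adds an integer state column (first match wins)."""
        used = {r.feature for leaf in self.states for r in leaf.rules}
        for feat in used:
            if feat not in visits.columns:
                raise DataError(f"visit table is missing required feature {feat!r}")
            if visits[feat].isna().any():
                raise DataError(f"visit table has missing values in required feature {feat!r}")
        n = len(visits)
        assigned = np.full(n, UNASSIGNED, dtype=int)
        unclaimed = np.ones(n, dtype=bool)
        for idx, leaf in enumerate(self.states):
            mask = unclaimed.copy()
            for rule in leaf.rules:
                mask &= rule.contains_array(visits[rule.feature].to_numpy(dtype=float))
            if leaf.pruned:
                assigned[mask] = UNASSIGNED
            else:
                assigned[mask] = idx
            unclaimed &= ~mask
        out = visits.copy()
        out[column] = assigned
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "min_occupancy": int(self.min_occupancy),
            "anomalies": list(self.anomalies),
            "states": [
                {
                    "label": s.label,
                    "occupancy": int(s.occupancy),
                    "predicted_mmse": None if s.predicted_mmse is None else float(s.predicted_mmse),
                    "pruned": bool(s.pruned),
                    "rules": [
                        {
                            "feature": r.feature,
                            "lo": None if math.isinf(r.lo) else float(r.lo),
                            "lo_closed": bool(r.lo_closed),
                            "hi": None if math.isinf(r.hi) else float(r.hi),
                            "hi_closed": bool(r.hi_closed),
                        }
                        for r in s.rules
                    ],
                }
                for s in self.states
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, payload: dict) -> "StateSpaceModel":
        states = [
            LeafState(
                label=s["label"],
                occupancy=int(s.get("occupancy", 0)),
                predicted_mmse=s.get("predicted_mmse"),
                pruned=bool(s.get("pruned", False)),
                rules=[
                    Rule(
                        feature=r["feature"],
                        lo=-math.inf if r.get("lo") is None else float(r["lo"]),
                        lo_closed=bool(r.get("lo_closed", False)),
                        hi=math.inf if r.get("hi") is None else float(r["hi"]),
                        hi_closed=bool(r.get("hi_closed", True)),
                    )
                    for r in s["rules"]
                ],
            )
            for s in payload["states"]
        ]
        return cls(
            states=states,
            features=list(payload["features"]),
            min_occupancy=int(payload.get("min_occupancy", DEFAULT_MIN_OCCUPANCY)),
            anomalies=list(payload.get("anomalies", [])),
        )

    @classmethod
    def load(cls, path) -> "StateSpaceModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def assign_state(model: StateSpaceModel, visit, check_unique: bool = False) -> int:
    """Functional alias for :meth:`StateSpaceModel.assign`."""
    return model.assign(visit, check_unique=check_unique)


# -- feature selection ---------------------------------------------------


@dataclass
class FeatureSelectionResult:
    """OLS coefficients/p-values for each candidate plus the selected subset."""

    table: pd.DataFrame  # columns: feature, coef, pvalue, selected
    dropped: list[str]
    alpha_sig: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "feature"].tolist()


def select_features(
    visits: pd.DataFrame,
    candidates: list[str] | None = None,
    alpha_sig: float = DEFAULT_ALPHA_SIG,
    target: str = "MMSE",
) -> FeatureSelectionResult:
    """Regress MMSE on the candidates and keep features with p < alpha_sig.

    Constant or exactly collinear candidates are excluded (with a warning)
    before the fit rather than producing unstable estimates.
    """
    if candidates is None:
        candidates = [f for f in DEFAULT_FEATURES if f in visits.columns]
    if len(candidates) < 2:
        raise DataError("select_features needs at least 2 candidate features")
    for col in candidates + [target]:
        if col not in visits.columns:
            raise DataError(f"visit table lacks column {col!r}")
        if visits[col].isna().any():
            raise DataError(f"column {col!r} has missing values; forward-fill first")
    dropped: list[str] = []
    kept: list[str] = []
    for feat in candidates:
        if visits[feat].nunique() <= 1:
            dropped.append(feat)
            logger.warning("select_features: dropping constant feature %r", feat)
            continue
        trial = kept + [feat]
        X = np.column_stack([np.ones(len(visits))] + [visits[f].to_numpy(float) for f in trial])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            dropped.append(feat)
            logger.warning("select_features: dropping collinear feature %r", feat)
            continue
        kept.append(feat)
    if not kept:
        raise DataError("no usable candidate features remain after exclusions")
    X = sm.add_constant(visits[kept].astype(float))
    fit = sm.OLS(visits[target].astype(float), X).fit()
    table = pd.DataFrame(
        {
            "feature": kept,
            "coef": [fit.params[f] for f in kept],
            "pvalue": [fit.pvalues[f] for f in kept],
        }
    )
    table["selected"] = table["pvalue"] < alpha_sig
    return FeatureSelectionResult(table=table, dropped=dropped, alpha_sig=alpha_sig)


# -- tree fitting ---------------------------------------------------------


def fit_state_tree(
    visits: pd.DataFrame,
    features: list[str],
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
    max_depth: int = DEFAULT_MAX_DEPTH,
    target: str = "MMSE",
) -> StateSpaceModel:
    """Binary regression tree of MMSE on the selected features; leaves = states.

    The minimum leaf size equals ``min_occupancy`` so every retained state is
    supported by at least that many training visits.  The fit is
    deterministic given the data and settings.
    """
    if not features:
        raise DataError("fit_state_tree requires a nonempty feature list")
    if min_occupancy < 1:
        raise ConfigurationError(f"min_occupancy must be >= 1, got {min_occupancy}")
    for col in features + [target]:
        if col not in visits.columns or visits[col].isna().any():
            raise DataError(f"feature {col!r} absent or incomplete; forward-fill first")
    if len(visits) < max(2, min_occupancy):
        logger.warning(
            "fit_state_tree: only %d visits for min_occupancy=%d; single-state model",
            len(visits),
            min_occupancy,
        )
        return StateSpaceModel(
            states=[LeafState("S0", rules=[], occupancy=len(visits),
                              predicted_mmse=float(visits[target].mean()) if len(visits) else None)],
            features=list(features),
            min_occupancy=min_occupancy,
        )
    X = visits[features].to_numpy(dtype=float)
    y = visits[target].to_numpy(dtype=float)
    tree = DecisionTreeRegressor(
        criterion="squared_error",
        min_samples_leaf=min_occupancy,
        max_depth=max_depth,
        random_state=0,
    ).fit(X, y)
    states = _extract_leaves(tree, features)
    model = StateSpaceModel(states=states, features=list(features), min_occupancy=min_occupancy)
    for leaf in model.states:
        if leaf.occupancy < min_occupancy:  # cannot happen with min_samples_leaf, kept as a guard
            leaf.pruned = True
    return model


def _extract_leaves(tree: DecisionTreeRegressor, features: list[str]) -> list[LeafState]:
    """Depth-first traversal turning each leaf into (a, b] interval rules."""
    t = tree.tree_
    leaves: list[LeafState] = []

    def recurse(node: int, bounds: dict[str, tuple[float, float]]):
        if t.children_left[node] == -1:  # leaf
            rules = [
                Rule(feature=f, lo=lo, lo_closed=False, hi=hi, hi_closed=True)
                for f, (lo, hi) in bounds.items()
                if not (math.isinf(lo) and math.isinf(hi))
            ]
            leaves.append(
                LeafState(
                    label=f"S{len(leaves)}",
                    rules=rules,
                    occupancy=int(t.n_node_samples[node]),
                    predicted_mmse=float(t.value[node].ravel()[0]),
                )
            )
            return
        feat = features[t.feature[node]]
        thr = float(t.threshold[node])
        lo, hi = bounds.get(feat, (-math.inf, math.inf))
        left = dict(bounds)
        left[feat] = (lo, min(hi, thr))
        recurse(t.children_left[node], left)
        right = dict(bounds)
        right[feat] = (max(lo, thr), hi)
        recurse(t.children_right[node], right)

    recurse(0, {})
    return leaves


# -- published rule fixture ----------------------------------------------

_INTERVAL_RE = re.compile(r"^\s*([\(\[])\s*([-\d.]*)\s*,\s*([-\d.]*)\s*([\)\]])\s*$")

_FIXTURE_COLUMNS = ["ADAS13", "RAVLT_IMMEDIATE", "RAVLT_LEARNING", "AGE", "CDRSB", "MOCA", "FDG"]


def parse_interval(feature: str, text: str) -> Rule:
    """Parse a printed interval such as ``(,19.5]``, ``[78,)`` or ``(25.2, 35.8)``."""
    m = _INTERVAL_RE.match(text)
    if not m:
        raise ConfigurationError(f"cannot parse interval {text!r} for feature {feature}")
    left, lo, hi, right = m.groups()
    return Rule(
        feature=feature,
        lo=-math.inf if lo == "" else float(lo),
        lo_closed=left == "[",
        hi=math.inf if hi == "" else float(hi),
        hi_closed=right == "]",
    )


def load_published_rules(cohort_name: str) -> StateSpaceModel:
    """Load the published per-cohort decision-tree rules shipped with the package.

    The rule table is encoded verbatim, including two anomalies it carries:
    the AD-Depression block lists the label S41 twice (two distinct rows),
    and the AD-Hypertension block's S33 region overlaps S27/S28.  The
    anomalies are reported on the returned model rather than silently
    resolved; assignment uses first-match order.
    """
    if cohort_name not in COHORT_NAMES:
        raise ConfigurationError(
            f"unknown cohort {cohort_name!r}; expected one of {COHORT_NAMES}"
        )
    # the hypertension and hypertension+depression cohorts share one rule block
    block = "AD_HTN" if cohort_name == "AD_DEP_HTN" else cohort_name
    path = importlib.resources.files("adrl.data") / "published_state_rules.csv"
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    rows = table[table["cohort"] == block]
    if rows.empty:
        raise ConfigurationError(f"no published rules for cohort {cohort_name!r}")
    states: list[LeafState] = []
    anomalies: list[str] = []
    seen_labels: set[str] = set()
    for _, row in rows.iterrows():
        label = row["state"]
        rules = [
            parse_interval(col, row[col]) for col in _FIXTURE_COLUMNS if row[col].strip()
        ]
        if label in seen_labels:
            anomalies.append(f"duplicate state label {label} encoded as a separate state")
        seen_labels.add(label)
        states.append(LeafState(label=label, rules=rules))
    if block == "AD_HTN":
        anomalies.append("S33 interval set overlaps the S27/S28 region; first match wins")
    model = StateSpaceModel(
        states=states,
        features=_FIXTURE_COLUMNS,
        min_occupancy=DEFAULT_MIN_OCCUPANCY,
        anomalies=anomalies,
    )
    return model
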