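import datetime as dt
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from injurychain.markov import (
    InjuryState,
    MarkovTransitionEstimator,
    classify_scenario,
    count_transitions,
    estimate_probabilities,
    filter_transitions,
    scenario_table,
    state_label,
    state_of,
)
from injurychain.preprocessing import preprocess
from injurychain.records import InjuryRecord
from injurychain.simulate import SyntheticCohortConfig, default_normalization_map, generate_cohort


def _transitions(pairs):
    """Tidy transition frame from ((part, nature), (part, nature)) pairs."""
    rows = []
    for i, ((fp, fn), (tp, tn)) in enumerate(pairs):
        rows.append(
            {
                "player_id": f"P{i}",
                "season_label": "2015-16",
                "from_date": pd.Timestamp("2015-09-01"),
                "from_body_part": fp,
                "from_nature": fn,
                "from_category": "",
                "to_date": pd.Timestamp("2015-10-01"),
                "to_body_part": tp,
                "to_nature": tn,
                "to_category": "",
                "gap_days": 30,
            }
        )
    from injurychain.sequences import TRANSITION_COLUMNS

    return pd.DataFrame(rows, columns=list(TRANSITION_COLUMNS))


def _rec(**kw):
    base = dict(player_id="P1", injury_date=dt.date(2015, 9, 1), body_part="Thigh|L", nature="muscle")
    base.update(kw)
    return InjuryRecord(**base)


class TestInjuryState:
    def test_part_nature_state(self):
        s = state_of(_rec(), "part_nature")
        assert s == InjuryState(level="part_nature", body_part="Thigh|L", nature="muscle")
        assert s.label == "Thigh|L:muscle"

    def test_categorization_state(self):
        s = state_of(_rec(category="Hamstring Muscle Injury"), "categorization")
        assert s.label == "Hamstring Muscle Injury"

    @pytest.mark.parametrize("cat", ["Unsure", "Others", ""])
    def test_excluded_categories_yield_none(self, cat):
        assert state_of(_rec(category=cat), "categorization") is None

    def test_level_field_discipline(self):
        with pytest.raises(ValueError):
            InjuryState(level="part_nature", body_part="Thigh|L")  # nature missing
        with pytest.raises(ValueError):
            InjuryState(level="categorization", category="ACL", body_part="Knee|L")

    def test_states_compare_by_level_and_fields(self):
        a = InjuryState(level="part_nature", body_part="Thigh|L", nature="muscle")
        b = InjuryState(level="part_nature", body_part="Thigh|R", nature="muscle")
        assert a != b and a == InjuryState(level="part_nature", body_part="Thigh|L", nature="muscle")


class TestCountTransitions:
    def test_simple_tally(self):
        t = _transitions([(("A", "x"), ("B", "x"))] * 2 + [(("A", "x"), ("C", "x"))])
        m = count_transitions(t)
        assert m.total_transitions == 3
        assert m.counts.loc["A:x", "B:x"] == 2 and m.counts.loc["A:x", "C:x"] == 1

    def test_empty_transition_list(self):
        m = count_transitions(_transitions([]))
        assert m.total_transitions == 0 and m.counts.size == 0

    def test_matches_brute_force_tally_on_random_pairs(self):
        rng = np.random.default_rng(0)
        parts = ["A", "B", "C"]
        natures = ["m", "t"]
        pairs = [
            ((parts[rng.integers(3)], natures[rng.integers(2)]), (parts[rng.integers(3)], natures[rng.integers(2)]))
            for _ in range(100)
        ]
        m = count_transitions(_transitions(pairs))
        brute = Counter((state_label(*f), state_label(*t)) for f, t in pairs)
        for (f, t), n in brute.items():
            assert m.counts.loc[f, t] == n
        assert m.total_transitions == 100


class TestEstimateProbabilities:
    def test_global_denominator(self):
        t = _transitions(
            [(("A", "x"), ("B", "x"))] * 2 + [(("A", "x"), ("C", "x")), (("B", "x"), ("C", "x"))]
        )
        est = estimate_probabilities(count_transitions(t), "global")
        p = est.set_index(["from_state", "to_state"])["p"]
        assert p[("A:x", "B:x")] == 0.50 and p[("A:x", "C:x")] == 0.25 and p[("B:x", "C:x")] == 0.25
        assert (est["n_denominator"] == 4).all()
        assert est["p"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_row_denominator(self):
        t = _transitions(
            [(("A", "x"), ("B", "x"))] * 2 + [(("A", "x"), ("C", "x")), (("B", "x"), ("C", "x"))]
        )
        est = estimate_probabilities(count_transitions(t), "row")
        p = est.set_index(["from_state", "to_state"])["p"]
        assert p[("A:x", "B:x")] == pytest.approx(2 / 3)
        assert p[("A:x", "C:x")] == pytest.approx(1 / 3)
        assert p[("B:x", "C:x")] == 1.0
        for _, row_est in est.groupby("from_state"):
            assert row_est["p"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_count_over_global_total(self):
        # 120 transitions of a cohort-wide 1,599 -> p = 0.0750
        t = _transitions([(("H", "m"), ("H", "m"))] * 120 + [(("A", "x"), ("B", "x"))] * 1479)
        est = estimate_probabilities(count_transitions(t), "global")
        p = est.set_index(["from_state", "to_state"])["p"]
        assert p[("H:m", "H:m")] == pytest.approx(0.0750, abs=5e-5)

    def test_empty_global_is_fatal(self):
        m = count_transitions(_transitions([]))
        with pytest.raises(ValueError, match="no transitions"):
            estimate_probabilities(m, "global")


class TestScenarios:
    def test_same_part_same_nature_is_reinjury(self):
        a = InjuryState(level="part_nature", body_part="Thigh|L", nature="muscle")
        assert classify_scenario(a, a) == "same_part_same_nature"

    def test_same_part_different_nature(self):
        a = InjuryState(level="part_nature", body_part="HipGroin|R", nature="muscle")
        b = InjuryState(level="part_nature", body_part="HipGroin|R", nature="tendon")
        assert classify_scenario(a, b) == "same_part_diff_nature"

    def test_different_parts_belong_only_to_any(self):
        a = InjuryState(level="part_nature", body_part="Thigh|L", nature="muscle")
        b = InjuryState(level="part_nature", body_part="Ankle|R", nature="sprain")
        assert classify_scenario(a, b) == "any"

    def test_mixed_level_is_fatal(self):
        a = InjuryState(level="part_nature", body_part="Thigh|L", nature="muscle")
        b = InjuryState(level="categorization", category="ACL")
        with pytest.raises(ValueError):
            classify_scenario(a, b)

    def test_scenario_partition_on_synthetic_transitions(self):
        cfg = SyntheticCohortConfig(n_players=150, seasons=["2015-16", "2016-17"], seed=3)
        rs, _ = generate_cohort(cfg)
        clean, _ = preprocess(rs, nmap=default_normalization_map(cfg.state_space))
        m = MarkovTransitionEstimator().fit(clean)
        est = m.estimates_
        s1 = scenario_table(est, "1")
        s2 = scenario_table(est, "2")
        assert scenario_table(est, "any").shape == est.shape
        assert set(s1.index).isdisjoint(s2.index)
        same_part = est[
            [f.rsplit(":", 1)[0] == t.rsplit(":", 1)[0] for f, t in zip(est.from_state, est.to_state)]
        ]
        assert set(s1.index) | set(s2.index) == set(same_part.index)

    def test_scenario_aliases(self):
        est = pd.DataFrame({"from_state": ["A:x"], "to_state": ["A:x"], "p": [1.0], "scenario": ["same_part_same_nature"]})
        assert len(scenario_table(est, "1")) == 1
        assert len(scenario_table(est, "all")) == 1
        with pytest.raises(ValueError):
            scenario_table(est, "weird")


class TestFilterTransitions:
    def test_strictly_below_threshold_removed(self):
        est = pd.DataFrame({"p": [0.0019, 0.002, 0.5]})
        out = filter_transitions(est, 0.002)
        assert out["p"].tolist() == [0.002, 0.5]

    def test_empty_input(self):
        assert len(filter_transitions(pd.DataFrame(columns=["p"]))) == 0


@pytest.fixture(scope="module")
def fitted():
    cfg = SyntheticCohortConfig(n_players=200, seasons=["2015-16", "2016-17"], seed=5)
    rs, _ = generate_cohort(cfg)
    clean, _ = preprocess(rs, nmap=default_normalization_map(cfg.state_space))
    return MarkovTransitionEstimator().fit(clean), clean


class TestEstimatorSurface:
    def test_sklearn_protocol(self, fitted):
        model, clean = fitted
        params = model.get_params()
        assert params["denominator"] == "global" and params["level"] == "part_nature"
        fresh = clone(model)
        fresh.set_params(denominator="row").fit(clean)
        for _, grp in fresh.estimates_.groupby("from_state"):
            assert grp["p"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_global_probabilities_sum_to_one(self, fitted):
        model, _ = fitted
        assert model.estimates_["p"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_predict_proba_rows_are_distributions(self, fitted):
        model, _ = fitted
        proba = model.predict_proba(model.states_[:3])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert model.predict_proba(["Nowhere:none"]).sum() == 0.0

    def test_predict_returns_known_state(self, fitted):
        model, _ = fitted
        assert model.predict([model.states_[0]])[0] in model.states_

    def test_estimates_filtering_is_reporting_only(self, fitted):
        model, _ = fitted
        full = model.estimates(filtered=False)
        shown = model.estimates(filtered=True)
        assert len(shown) <= len(full)
        assert full["p"].sum() == pytest.approx(1.0, abs=1e-12)  # denominators untouched

    def test_categorization_level_drops_excluded_labels(self):
        cfg = SyntheticCohortConfig(n_players=200, seasons=["2015-16", "2016-17"], seed=6)
        rs, _ = generate_cohort(cfg)
        clean, _ = preprocess(rs, nmap=default_normalization_map(cfg.state_space))
        m = MarkovTransitionEstimator(level="categorization").fit(clean)
        assert "Unsure" not in m.states_ and "Others" not in m.states_
        assert (m.estimates_["scenario"] == "any").all()
        assert m.n_transitions_ <= len(m.transitions_)
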