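import pandas as pd
import pytest
from hypothesis import given, strategies as st

from injurychain.preprocessing import (
    InjuryPreprocessor,
    NormalizationMap,
    drop_contact,
    drop_missing_core,
    drop_single_injury_player_seasons,
    merge_side_into_body_part,
    normalize_labels,
    preprocess,
)
from injurychain.simulate import SyntheticCohortConfig, default_normalization_map, generate_cohort


class TestNormalizeLabels:
    def test_mapping_applied(self, rs_factory):
        rs = rs_factory([{"body_part": "Thigh muscles"}])
        nmap = NormalizationMap(body_part={"Thigh muscles": "Thigh"})
        out = normalize_labels(rs, nmap)
        assert out.frame["body_part"].iloc[0] == "Thigh"

    def test_canonical_records_unchanged(self, rs_factory):
        rs = rs_factory([{"body_part": "Thigh"}])
        nmap = NormalizationMap(body_part={"thigh": "Thigh"})
        out = normalize_labels(rs, nmap)
        pd.testing.assert_frame_equal(out.frame, rs.frame)

    def test_unmapped_label_warns_in_lenient_mode(self, rs_factory):
        rs = rs_factory([{"body_part": "Shin"}])
        nmap = NormalizationMap(body_part={"thigh": "Thigh"})
        with pytest.warns(UserWarning, match="Shin"):
            out = normalize_labels(rs, nmap)
        assert out.frame["body_part"].iloc[0] == "Shin"

    def test_unmapped_label_fatal_in_strict_mode(self, rs_factory):
        rs = rs_factory([{"body_part": "Shin"}])
        nmap = NormalizationMap(body_part={"thigh": "Thigh"}, strict=True)
        with pytest.raises(ValueError, match="Shin"):
            normalize_labels(rs, nmap)

    def test_non_idempotent_map_rejected(self):
        with pytest.raises(ValueError, match="idempotent"):
            NormalizationMap(body_part={"a": "b", "b": "c"})

    def test_yaml_round_trip(self, tmp_path):
        nmap = NormalizationMap(body_part={"thigh": "Thigh"}, nature={"Muscle": "muscle"})
        nmap.to_file(tmp_path / "map.yaml")
        back = NormalizationMap.from_file(tmp_path / "map.yaml")
        assert back.body_part == nmap.body_part and back.nature == nmap.nature


class TestDropRules:
    def test_missing_core_removed_and_counted(self, rs_factory):
        rs = rs_factory([{}] * 8 + [{"body_part": ""}] * 2)
        out, report = drop_missing_core(rs)
        assert len(out) == 8 and report.removed == {"missing_core": 2}

    def test_missing_side_only_is_retained(self, rs_factory):
        rs = rs_factory([{"side": "unspecified"}])
        out, _ = drop_missing_core(rs)
        assert len(out) == 1  # side is not a core field

    def test_contact_yes_removed(self, rs_factory):
        rs = rs_factory([{"contact": "yes"}] * 4 + [{}] * 6)
        out, report = drop_contact(rs)
        assert len(out) == 6 and report.removed == {"contact": 4}

    def test_all_contact_gives_empty_set(self, rs_factory):
        out, _ = drop_contact(rs_factory([{"contact": "yes"}] * 3))
        assert len(out) == 0

    def test_unknown_contact_retained_unless_flagged(self, rs_factory):
        rs = rs_factory([{"contact": "unknown"}])
        assert len(drop_contact(rs)[0]) == 1
        assert len(drop_contact(rs, drop_unknown=True)[0]) == 0


class TestMergeSide:
    @pytest.mark.parametrize(
        "side,token", [("left", "L"), ("right", "R"), ("bilateral", "B"), ("unspecified", "U")]
    )
    def test_side_token_folded_into_body_part(self, rs_factory, side, token):
        out = merge_side_into_body_part(rs_factory([{"body_part": "Thigh", "side": side}]))
        assert out.frame["body_part"].iloc[0] == f"Thigh|{token}"
        assert out.frame["body_part_raw"].iloc[0] == "Thigh"

    def test_left_and_right_become_distinct_parts(self, rs_factory):
        out = merge_side_into_body_part(
            rs_factory([{"side": "left"}, {"side": "right"}])
        )
        assert out.frame["body_part"].nunique() == 2

    def test_merge_is_idempotent(self, rs_factory):
        once = merge_side_into_body_part(rs_factory([{}]))
        twice = merge_side_into_body_part(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)


class TestSingleInjuryRule:
    def test_lone_injury_removed(self, rs_factory):
        rs = rs_factory([{"player_id": "P1", "injury_date": "2015-09-01"}])
        out, report = drop_single_injury_player_seasons(rs)
        assert len(out) == 0 and report.removed == {"single_injury": 1}

    def test_grouping_is_per_season(self, rs_factory):
        rs = rs_factory(
            [
                {"player_id": "P1", "injury_date": "2015-09-01"},
                {"player_id": "P1", "injury_date": "2015-11-01"},
                {"player_id": "P1", "injury_date": "2016-09-01"},  # next season, alone
            ]
        )
        out, report = drop_single_injury_player_seasons(rs)
        assert len(out) == 2 and report.removed == {"single_injury": 1}
        # brute-force check of the survivors
        labels = out.frame["injury_date"].dt.year
        assert set(labels) == {2015}

    def test_identity_when_all_groups_large_enough(self, rs_factory):
        rs = rs_factory(
            [{"player_id": "P1", "injury_date": d} for d in ("2015-09-01", "2015-10-01")]
        )
        out, report = drop_single_injury_player_seasons(rs)
        assert len(out) == 2 and report.removed == {"single_injury": 0}


def _brute_force_preprocess(rows: list[dict]) -> int:
    """Independent re-application of the cleaning rules on plain dicts."""
    kept = [r for r in rows if r.get("player_id", "P") and r.get("body_part", "B")]
    kept = [r for r in kept if r.get("contact", "no") != "yes"]
    from collections import Counter

    while True:
        sizes = Counter((r["player_id"], r["injury_date"][:4]) for r in kept)  # same-year seasons here
        new = [r for r in kept if sizes[(r["player_id"], r["injury_date"][:4])] >= 2]
        if len(new) == len(kept):
            return len(new)
        kept = new


class TestPreprocessPipeline:
    def test_engineered_fixture_matches_brute_force(self, rs_factory):
        # all dates inside one season so the brute-force year grouping is valid
        rows = []
        for i in range(8):
            rows.append({"player_id": f"P{i % 4}", "injury_date": f"2015-09-{i + 1:02d}"})
        rows += [{"player_id": "", "injury_date": "2015-09-20"}] * 2  # missing core
        rows += [{"player_id": "P0", "injury_date": "2015-09-21", "contact": "yes"}] * 3
        rows += [{"player_id": "P7", "injury_date": "2015-09-22"}]  # lone injury
        rows += [{"player_id": "P8", "injury_date": "2015-09-23", "body_part": ""}]
        rs = rs_factory(rows)
        out, report = preprocess(rs)
        assert len(out) == _brute_force_preprocess(rows)
        assert report.n_before - report.n_after == sum(report.removed.values())

    def test_clean_fixture_is_identity_on_counts(self, rs_factory):
        rs = rs_factory(
            [{"player_id": "P1", "injury_date": d} for d in ("2015-09-01", "2015-10-01")]
        )
        out, report = preprocess(rs)
        assert len(out) == 2 and sum(report.removed.values()) == 0

    def test_contact_rule_attribution_precedes_single_injury(self, rs_factory):
        # a contact injury that is also the player's only injury counts as contact
        rs = rs_factory([{"player_id": "P1", "contact": "yes"}])
        _, report = preprocess(rs)
        assert report.removed["contact"] == 1
        assert report.removed["single_injury"] == 0

    def test_contact_removal_can_create_new_single_injury_seasons(self, rs_factory):
        rs = rs_factory(
            [
                {"player_id": "P1", "injury_date": "2015-09-01"},
                {"player_id": "P1", "injury_date": "2015-10-01", "contact": "yes"},
            ]
        )
        out, report = preprocess(rs)
        assert len(out) == 0
        assert report.removed == {"missing_core": 0, "contact": 1, "single_injury": 1}

    @given(seed=st.integers(0, 10_000))
    def test_idempotence_and_conservation_on_synthetic_cohorts(self, seed):
        cfg = SyntheticCohortConfig(n_players=40, seasons=["2015-16", "2016-17"], seed=seed)
        rs, _ = generate_cohort(cfg)
        nmap = default_normalization_map(cfg.state_space)
        once, report = preprocess(rs, nmap=nmap)
        report.check()
        assert report.n_before - report.n_after == sum(report.removed.values())
        twice, report2 = preprocess(once, nmap=nmap)
        pd.testing.assert_frame_equal(twice.frame, once.frame)
        assert sum(report2.removed.values()) == 0

    def test_transformer_surface_matches_function(self, rs_factory):
        rs = rs_factory(
            [{"player_id": "P1", "injury_date": d} for d in ("2015-09-01", "2015-10-01")]
            + [{"player_id": "P2", "contact": "yes"}]
        )
        pre = InjuryPreprocessor()
        out = pre.fit_transform(rs)
        expected, report = preprocess(rs)
        pd.testing.assert_frame_equal(out.frame, expected.frame)
        assert pre.report_.removed == report.removed
        assert InjuryPreprocessor(drop_unknown_contact=True).get_params()["drop_unknown_contact"]
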