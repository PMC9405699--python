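"""Rubric structure and item-level scoring semantics."""
import math

import pytest

from gaitool.measured import MONOTONE_ITEMS
from gaitool.rubric import (ItemInput, MissingMeasurementError, ScoringError,
                            load_rubric, score_item)


def _measured(item_id, **measurements):
    return ItemInput(item_id=item_id, mode="measured", measurements=measurements)


class TestRubricStructure:
    def test_31_items_maxima_sum_62(self, rubric):
        assert len(rubric) == 31
        assert sum(it.max_score for it in rubric) == 62
        assert [it.id for it in rubric] == list(range(1, 32))

    def test_sections(self, rubric):
        assert all(it.section == "stance_and_swing" for it in rubric[:4])
        assert all(it.section == "stance" for it in rubric[4:18])
        assert all(it.section == "swing" for it in rubric[18:])

    def test_branch_structure(self, by_id):
        assert {b.label for b in by_id[13].branches} == {"A", "B", "C", "D"}
        for iid in (11, 12, 15):
            assert {b.label for b in by_id[iid].branches} == {"A", "B"}
        for iid in set(range(1, 32)) - {11, 12, 13, 15}:
            assert [b.label for b in by_id[iid].branches] == ["default"]

    def test_one_level_zero_per_branch(self, rubric):
        for it in rubric:
            for br in it.branches:
                assert sum(1 for lv in br.levels if lv.score == 0) == 1

    def test_duplicate_scores_have_distinct_codes(self, by_id):
        # e.g. weight shift has two distinct ways to score 2
        codes = {lv.code for br in by_id[7].branches for lv in br.levels
                 if lv.score == 2}
        assert codes == {"almost_none", "excessive"}
        for iid in (10, 15, 18, 22, 23, 24, 25, 28, 31):
            it = by_id[iid]
            pairs = [(br.label, lv.score) for br in it.branches for lv in br.levels]
            assert len(pairs) > len(set(pairs)) or len(it.branches) > 1


class TestWorkedLevels:
    """Directly printed threshold examples."""

    @pytest.mark.parametrize("item_id,meas,expected", [
        (2, {"elbow_flexion_mean": 100.0}, 2),   # > 90 deg elbow flexion
        (2, {"elbow_flexion_mean": 60.0}, 1),
        (2, {"elbow_flexion_mean": 10.0}, 0),
        (26, {"knee_flexion_initial_swing_max": 50.0}, 0),  # 40-60 normal
        (26, {"knee_flexion_initial_swing_max": 20.0}, 1),  # >=15 but <40
        (26, {"knee_flexion_initial_swing_max": 0.0}, 3),   # never flexes
        (27, {"knee_flexion_midswing_max": 60.0}, 0),       # 60 +- 4
        (27, {"knee_flexion_midswing_max": 50.0}, 1),
        (27, {"knee_flexion_midswing_max": 30.0}, 2),
        (27, {"knee_flexion_midswing_max": 10.0}, 3),
    ])
    def test_printed_thresholds(self, by_id, item_id, meas, expected):
        assert score_item(by_id[item_id], _measured(item_id, **meas)).score == expected

    def test_item11_branches_from_sign(self, by_id):
        flex = score_item(by_id[11], _measured(11, knee_flexion_at_initial_contact=20.0))
        assert (flex.branch_label, flex.score) == ("A", 2)
        hyper = score_item(by_id[11], _measured(11, knee_flexion_at_initial_contact=-10.0))
        assert (hyper.branch_label, hyper.score) == ("B", 1)

    def test_item7_duplicate_score_levels_resolve_by_descriptor(self, by_id):
        none = score_item(by_id[7], _measured(7, weight_shift_mm=2.0))
        exc = score_item(by_id[7], _measured(7, weight_shift_mm=60.0))
        assert none.score == exc.score == 2
        assert (none.descriptor_code, exc.descriptor_code) == ("almost_none", "excessive")


class TestGapsAndFlags:
    def test_abnormal_gap_never_scores_zero(self, by_id):
        # above the printed normal band for initial-swing knee flexion
        sc = score_item(by_id[26], _measured(26, knee_flexion_initial_swing_max=70.0,
                                             knee_flexion_cycle_max=70.0))
        assert sc.score > 0 and sc.flagged_for_review

    def test_weight_shift_gap_maps_to_nearest_abnormal(self, by_id):
        sc = score_item(by_id[7], _measured(7, weight_shift_mm=40.0))
        assert sc.flagged_for_review
        assert sc.descriptor_code == "excessive" and sc.score == 2

    def test_every_finite_vector_scores(self, by_id):
        for v in (-500.0, -3.3, 0.0, 4.99, 5.0, 61.7, 400.0):
            sc = score_item(by_id[27], _measured(27, knee_flexion_midswing_max=v))
            assert sc.score in (0, 1, 2, 3)


class TestMonotonicity:
    @pytest.mark.parametrize("item_id", MONOTONE_ITEMS)
    def test_scores_never_decrease_away_from_normal(self, by_id, item_id):
        item = by_id[item_id]
        meas = item.primary_measurement
        lv0 = item.branches[0].level0
        iv = lv0.interval
        lo = iv.lo if math.isfinite(iv.lo) else iv.hi - 10
        hi = iv.hi if math.isfinite(iv.hi) else iv.lo + 10
        center = (lo + hi) / 2
        for direction in (+1, -1):
            last = -1
            for k in range(241):
                value = center + direction * k * 0.5
                extras = ({"knee_flexion_cycle_max": max(value, 50.0)}
                          if item_id == 26 else {})
                sc = score_item(item, _measured(item_id, **{meas: value}, **extras))
                assert sc.score >= last, (item_id, value, sc.score, last)
                last = sc.score


class TestInputContract:
    def test_missing_measurement_named(self, by_id):
        with pytest.raises(MissingMeasurementError, match="knee_flexion_midswing_max"):
            score_item(by_id[27], _measured(27, something_else=1.0))

    def test_unknown_observed_descriptor(self, by_id):
        with pytest.raises(ScoringError, match="not in item"):
            score_item(by_id[2], ItemInput(2, "observed", observed_code="nope"))

    def test_observed_mode_lookup_and_checkboxes(self, by_id):
        sc = score_item(by_id[1], ItemInput(1, "observed",
                                            observed_code="abnormal_position",
                                            checkboxes=("depressed", "retracted")))
        assert sc.score == 1 and sc.checkboxes == ("depressed", "retracted")
        with pytest.raises(ScoringError, match="checkbox"):
            score_item(by_id[1], ItemInput(1, "observed",
                                           observed_code="abnormal_position",
                                           checkboxes=("sideways",)))

    def test_exactly_one_input_mode(self):
        with pytest.raises(ScoringError):
            ItemInput(2, "measured")
        with pytest.raises(ScoringError):
            ItemInput(2, "observed")

    def test_determinism(self, by_id):
        inp = _measured(24, hip_flexion_swing_max=25.0, hip_flexion_at_toe_off=2.0,
                        hip_abduction_swing_dev=7.0)
        a = score_item(by_id[24], inp)
        b = score_item(by_id[24], inp)
        assert (a.score, a.descriptor_code) == (b.score, b.descriptor_code) == (2, "circumduction")
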