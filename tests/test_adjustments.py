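"""Administration adjustments: orthosis midpoints, device minimums,
physical-assist escalation, footwear exclusions."""
import copy

import pytest

from gaitool.adjustments import (ContextFlags, apply_adjustments,
                                 device_minimums, footwear_exclusions,
                                 orthosis_adjustment)
from gaitool.rubric import ItemInput, score_sheet


def _all_normal_inputs(rubric):
    return [ItemInput(item_id=it.id, mode="observed",
                      observed_code="normal", branch_label=it.branches[0].label)
            for it in rubric]


@pytest.fixture
def normal_sheet(rubric):
    return score_sheet(_all_normal_inputs(rubric), ContextFlags())


class TestOrthosisMidpoint:
    def test_afo_item16_scores_2(self, by_id):
        # abnormal set {1,2,3} -> midpoint 2 (the printed AFO example)
        assert orthosis_adjustment(by_id[16]) == 2

    def test_single_abnormal_level(self, by_id):
        assert orthosis_adjustment(by_id[30]) == 1  # abnormal {1}

    def test_even_cardinality_rounds_up(self, by_id):
        assert orthosis_adjustment(by_id[5]) == 2  # abnormal {1,2} -> ceil(1.5)

    def test_applied_to_sheet(self, rubric):
        ctx = ContextFlags(orthosis="AFO")
        sheet = score_sheet(_all_normal_inputs(rubric), ctx)
        sc = sheet.item(16)
        assert sc.score == 2 and sc.adjusted and "orthosis" in sc.adjustment_reason
        assert sc.raw_score == 0  # audit trail keeps the pre-adjustment score


class TestDeviceMinimums:
    def test_cane_floors_items_7_and_8(self, rubric):
        sheet = score_sheet(_all_normal_inputs(rubric),
                            ContextFlags(assistive_device="cane"))
        assert sheet.item(7).score == 1 and sheet.item(8).score == 1
        assert sheet.item(7).adjusted and sheet.item(8).adjusted

    def test_already_abnormal_score_unchanged(self, rubric):
        inputs = [i for i in _all_normal_inputs(rubric) if i.item_id != 7]
        inputs.append(ItemInput(item_id=7, mode="observed", observed_code="excessive"))
        sheet = score_sheet(inputs, ContextFlags(assistive_device="cane"))
        assert sheet.item(7).score == 2  # already >= minimum

    def test_no_device_no_change(self, normal_sheet):
        before = copy.deepcopy(normal_sheet)
        device_minimums(normal_sheet, ContextFlags())
        assert normal_sheet == before


class TestAssistEscalation:
    def test_moderate_assist_item4_max_item5_max(self, rubric):
        sheet = score_sheet(_all_normal_inputs(rubric),
                            ContextFlags(assist="moderate_or_2plus"))
        assert sheet.item(4).score == 3  # printed example
        assert sheet.item(5).score == 2  # printed example
        assert sheet.item(7).score == 2

    def test_minimal_assist_uses_midpoints(self, rubric):
        sheet = score_sheet(_all_normal_inputs(rubric),
                            ContextFlags(assist="minimal_1"))
        assert sheet.item(4).score == 2  # abnormal {1,2,3} midpoint
        assert sheet.item(5).score == 2  # abnormal {1,2} ceil midpoint

    def test_minimum_rule_never_lowers(self, rubric):
        inputs = [i for i in _all_normal_inputs(rubric) if i.item_id != 4]
        inputs.append(ItemInput(item_id=4, mode="observed",
                                observed_code="combined_malalignment",
                                checkboxes=("flexion", "left")))
        sheet = score_sheet(inputs, ContextFlags(assist="minimal_1"))
        assert sheet.item(4).score == 3

    def test_standby_assist_notes_only(self, rubric):
        sheet = score_sheet(_all_normal_inputs(rubric), ContextFlags(assist="standby"))
        assert sheet.total == 0
        assert "stand-by assist" in sheet.metadata.notes


class TestFootwearExclusions:
    def test_shoes_exclude_toe_items(self, rubric):
        inputs = [i for i in _all_normal_inputs(rubric) if i.item_id not in (18, 31)]
        sheet = score_sheet(inputs, ContextFlags(footwear="shoes"))
        assert sheet.item(18).excluded and sheet.item(31).excluded
        assert sheet.max_possible == 60

    def test_barefoot_no_exclusions(self, normal_sheet):
        assert not any(sc.excluded for sc in normal_sheet.item_scores)
        assert normal_sheet.max_possible == 62

    def test_max_total_with_shoes_is_60_of_60(self, rubric):
        inputs = []
        for it in rubric:
            if it.id in (18, 31):
                continue
            best = max(((br, lv) for br in it.branches for lv in br.levels),
                       key=lambda pair: pair[1].score)
            inputs.append(ItemInput(item_id=it.id, mode="observed",
                                    observed_code=best[1].code,
                                    branch_label=best[0].label))
        sheet = score_sheet(inputs, ContextFlags(footwear="shoes"))
        assert (sheet.total, sheet.max_possible) == (60, 60)


class TestPipelineProperties:
    def test_every_item_maximal_totals_62(self, rubric):
        inputs = []
        for it in rubric:
            best = max(((br, lv) for br in it.branches for lv in br.levels),
                       key=lambda pair: pair[1].score)
            inputs.append(ItemInput(item_id=it.id, mode="observed",
                                    observed_code=best[1].code,
                                    branch_label=best[0].label))
        sheet = score_sheet(inputs, ContextFlags())
        assert (sheet.total, sheet.max_possible) == (62, 62)

    def test_adjustments_idempotent(self, rubric):
        ctx = ContextFlags(assistive_device="walker", orthosis="AFO",
                           assist="minimal_1", footwear="shoes")
        inputs = [i for i in _all_normal_inputs(rubric) if i.item_id not in (18, 31)]
        sheet = score_sheet(inputs, ctx)
        once = copy.deepcopy(sheet)
        apply_adjustments(sheet, ctx)
        assert sheet == once

    def test_adjusted_items_carry_reasons(self, rubric):
        ctx = ContextFlags(assistive_device="cane", orthosis="AFO", footwear="shoes")
        inputs = [i for i in _all_normal_inputs(rubric) if i.item_id not in (18, 31)]
        sheet = score_sheet(inputs, ctx)
        for sc in sheet.item_scores:
            if sc.adjusted:
                assert sc.adjustment_reason
            if sc.excluded:
                assert sc.exclusion_reason

    def test_duplicate_and_missing_inputs_rejected(self, rubric):
        inputs = _all_normal_inputs(rubric)
        with pytest.raises(Exception, match="duplicate"):
            score_sheet(inputs + [inputs[0]], ContextFlags())
        with pytest.raises(Exception, match=r"\b12\b"):
            score_sheet([i for i in inputs if i.item_id != 12], ContextFlags())
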