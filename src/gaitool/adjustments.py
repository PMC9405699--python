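"""Context-dependent score adjustments from the instrument's administration
rules: orthosis midpoint scores, assistive-device minimums, physical-assist
escalation, and footwear exclusions.

All adjustments have "at a minimum" semantics -- they never lower a score --
and the pipeline is idempotent.  Raw pre-adjustment scores are retained on
each item for audit, and every adjusted or excluded item carries a
machine-readable reason.

Order of application: item scoring -> orthosis -> device minimums -> assist
adjustments -> footwear exclusions -> totals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .rubric import ItemDefinition, ScoreSheet, load_rubric

#: default item set affected by an ankle-foot orthosis (the instrument gives
#: only the item-16 example; ankle/toe items on the braced limb)
AFO_DEFAULT_ITEMS = (15, 16, 17, 29, 30)

#: items "pertaining to trunk alignment/posture and weight shifting" for the
#: physical-assist rule (printed examples name items 4 and 5)
ASSIST_ITEMS_DEFAULT = (4, 5, 6, 7, 19, 20)

#: items floored at 1 when any assistive device is used
DEVICE_MINIMUM_ITEMS = (7, 8)

#: toe-position items excluded when shoes are worn
FOOTWEAR_EXCLUDED_ITEMS = (18, 31)


@dataclass
class ContextFlags:
    """Administration context parsed from the form header or CLI options."""

    assistive_device: str = "none"      # none | cane | walker | other
    orthosis: str = "none"              # none | AFO | KAFO | other
    orthosis_items: tuple[int, ...] = ()  # items the worn orthosis relates to
    footwear: str = "barefoot"          # barefoot | shoes
    assist: str = "none"                # none | standby | minimal_1 | moderate_or_2plus
    side: str = "right"
    assist_items: tuple[int, ...] = ASSIST_ITEMS_DEFAULT

    def __post_init__(self):
        if self.orthosis != "none" and not self.orthosis_items:
            self.orthosis_items = AFO_DEFAULT_ITEMS if self.orthosis == "AFO" else ()


def orthosis_adjustment(item: ItemDefinition) -> int:
    """Midpoint of the item's abnormal (nonzero) score values; non-integer
    midpoints round up, consistent with the rule's "at a minimum" language."""
    ab = item.abnormal_scores
    if not ab:
        raise ValueError(f"item {item.id} has no abnormal score levels")
    return math.ceil((ab[0] + ab[-1]) / 2)


def _floor_item(sheet: ScoreSheet, item: ItemDefinition, minimum: int,
                reason: str) -> None:
    sc = sheet.item(item.id)
    if sc.excluded or sc.score >= minimum:
        return
    if sc.raw_score is None:
        sc.raw_score = sc.score
    if sc.score == 0:
        # the floored score needs a descriptor: the mildest abnormal level
        # whose score meets the floor
        levels = sorted((lv for br in item.branches for lv in br.levels
                         if lv.score >= minimum), key=lambda lv: lv.score)
        sc.descriptor_code = levels[0].code
        sc.branch_label = next(br.label for br in item.branches
                               if levels[0] in br.levels)
    sc.score = minimum
    sc.adjusted = True
    sc.adjustment_reason = reason


def apply_orthosis(sheet: ScoreSheet, context: ContextFlags,
                   rubric: Optional[list[ItemDefinition]] = None) -> ScoreSheet:
    if context.orthosis == "none":
        return sheet
    by_id = {it.id: it for it in (rubric or load_rubric())}
    for iid in context.orthosis_items:
        item = by_id[iid]
        _floor_item(sheet, item, orthosis_adjustment(item),
                    f"orthosis_midpoint:{context.orthosis}")
    return sheet


def device_minimums(sheet: ScoreSheet, context: ContextFlags,
                    rubric: Optional[list[ItemDefinition]] = None) -> ScoreSheet:
    """With any assistive device, weight shift (7) and the Trendelenburg
    item (8) cannot score normal: minimum abnormal score of 1."""
    if context.assistive_device == "none":
        return sheet
    by_id = {it.id: it for it in (rubric or load_rubric())}
    for iid in DEVICE_MINIMUM_ITEMS:
        _floor_item(sheet, by_id[iid], 1,
                    f"device_minimum:{context.assistive_device}")
    return sheet


def assist_adjustments(sheet: ScoreSheet, context: ContextFlags,
                       rubric: Optional[list[ItemDefinition]] = None) -> ScoreSheet:
    """Physical-assist escalation on trunk-alignment/posture and weight-shift
    items: minimal assist of one -> at least the midpoint of the abnormal
    scores; moderate assist (or two people) -> the highest abnormal score.
    Stand-by assist changes no scores, only a report note."""
    if context.assist in ("none", ""):
        return sheet
    if context.assist == "standby":
        note = "stand-by assist"
        if note not in sheet.metadata.notes:
            sheet.metadata.notes.append(note)
        return sheet
    by_id = {it.id: it for it in (rubric or load_rubric())}
    for iid in context.assist_items:
        item = by_id[iid]
        if context.assist == "minimal_1":
            _floor_item(sheet, item, orthosis_adjustment(item), "assist_midpoint:minimal_1")
        elif context.assist == "moderate_or_2plus":
            _floor_item(sheet, item, item.max_score, "assist_maximum:moderate_or_2plus")
        else:
            raise ValueError(f"unknown assist level {context.assist!r}")
    return sheet


def footwear_exclusions(sheet: ScoreSheet, context: ContextFlags,
                        rubric: Optional[list[ItemDefinition]] = None) -> ScoreSheet:
    """Shoes hide toe position: toe items are not scored and the total
    possible score is adjusted."""
    if context.footwear != "shoes":
        return sheet
    for iid in FOOTWEAR_EXCLUDED_ITEMS:
        sc = sheet.item(iid)
        if not sc.excluded:
            sc.excluded = True
            sc.exclusion_reason = "not scored - footwear (toe position not visible)"
    return sheet


def apply_adjustments(sheet: ScoreSheet, context: ContextFlags,
                      rubric: Optional[list[ItemDefinition]] = None) -> ScoreSheet:
    """Full adjustment pipeline in the documented order, then totals."""
    rubric = rubric or load_rubric()
    apply_orthosis(sheet, context, rubric)
    device_minimums(sheet, context, rubric)
    assist_adjustments(sheet, context, rubric)
    footwear_exclusions(sheet, context, rubric)
    sheet.metadata.device = context.assistive_device
    sheet.metadata.orthosis = context.orthosis
    sheet.metadata.assist = context.assist
    sheet.metadata.footwear = context.footwear
    sheet.recompute_totals(rubric)
    return sheet
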