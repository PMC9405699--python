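"""Measured-mode item classifiers.

Maps a dictionary of named kinematic measurements (read at each item's
temporal event by the kinematics module, or analytically from the normative
template by the simulator's oracle) to an ordinal item score.

Two families:

* *generic* items whose levels are realized intervals on a single
  measurement -- resolved directly from the packaged rubric's intervals,
  checked most-severe-first so that duplicate-score levels keep their
  printed precedence;
* *pattern* items whose printed levels describe a movement pattern
  (foot-flat contact, knee buckling, hiking, ...) -- resolved by explicit
  decision rules built from the same realized thresholds, documented in the
  methods note.

Any finite measurement vector yields a score.  A value that is abnormal but
not covered by a printed level maps to the nearest abnormal level (distance
to its realized interval, ties to the milder score) and is flagged for
review -- an abnormal performance can never score 0.
"""
from __future__ import annotations

import math
from typing import Callable, Optional

from .config import DEFAULT_CONFIG, EngineConfig
from .rubric import Branch, ItemDefinition, ItemScore, ScoreLevel


def _mk(item: ItemDefinition, branch: str, code: str,
        checkboxes: tuple[str, ...] = (), flagged: bool = False) -> ItemScore:
    br, lv = item.find_level(code, branch)
    return ItemScore(item.id, br.label, lv.score, lv.code,
                     checkboxes=checkboxes, flagged_for_review=flagged,
                     raw_score=lv.score)


def _other_side(side: str) -> str:
    return "left" if side == "right" else "right"


# ---------------------------------------------------------------------------
# generic single-measurement interval items

def _classify_generic(item: ItemDefinition, branch: Branch, m: dict,
                      checkboxes: tuple[str, ...] = ()) -> ItemScore:
    levels = [lv for lv in branch.levels if lv.interval is not None]
    # most severe first; stable within equal scores (printed order)
    for lv in sorted(levels, key=lambda lv: -lv.score):
        if lv.interval.measurement in m and lv.interval.contains(m[lv.interval.measurement]):
            return ItemScore(item.id, branch.label, lv.score, lv.code,
                             checkboxes=checkboxes, raw_score=lv.score)
    # rubric gap: nearest abnormal level, ties to the milder score, flagged
    abnormal = [lv for lv in levels if lv.score > 0 and lv.interval.measurement in m]
    if not abnormal:
        raise ValueError(f"item {item.id}: no abnormal interval level matches input")
    lv = min(abnormal, key=lambda lv: (lv.interval.distance(m[lv.interval.measurement]),
                                       lv.score))
    return ItemScore(item.id, branch.label, lv.score, lv.code,
                     checkboxes=checkboxes, flagged_for_review=True,
                     raw_score=lv.score)


def _sign_checkbox(value: float, pos: str, neg: str) -> tuple[str, ...]:
    if value > 0:
        return (pos,)
    if value < 0:
        return (neg,)
    return ()


# ---------------------------------------------------------------------------
# pattern classifiers

def _item_1(item, m, cfg: EngineConfig, side):
    # Static shoulder-angle offset heuristic; the printed sub-descriptors
    # (depressed/elevated/retracted/protracted) need direct observation, so
    # an abnormal measured result is always flagged for a rater's review.
    if abs(m["shoulder_static_offset"]) <= cfg.heuristics.shoulder_static_abnormal_deg:
        return _mk(item, "default", "normal")
    return _mk(item, "default", "abnormal_position", flagged=True)


def _item_3(item, m, cfg, side):
    h = cfg.heuristics
    if m["shoulder_excursion"] < h.arm_swing_fraction * h.template_shoulder_excursion_deg:
        return _mk(item, "default", "reduced_or_absent")
    return _mk(item, "default", "normal")


def _item_4(item, m, cfg, side):
    thr = cfg.heuristics.trunk_static_abnormal_deg
    s, c = m["trunk_sagittal_static"], m["trunk_coronal_static"]
    sag, cor = abs(s) > thr, abs(c) > thr
    sag_cb = _sign_checkbox(s, "flexion", "extension") if sag else ()
    cor_cb = (_sign_checkbox(c, side, _other_side(side)) if cor else ())
    if sag and cor:
        return _mk(item, "default", "combined_malalignment", sag_cb + cor_cb)
    if cor:
        return _mk(item, "default", "lateral_malalignment", cor_cb)
    if sag:
        return _mk(item, "default", "sagittal_malalignment", sag_cb)
    return _mk(item, "default", "normal")


def _trunk_dynamic(item, m, cfg, side, measurement, sagittal: bool):
    v = m[measurement]
    cb = (_sign_checkbox(v, "flexes", "extends") if sagittal
          else _sign_checkbox(v, side, _other_side(side)))
    score = _classify_generic(item, item.branches[0], m)
    if score.score == 0:
        cb = ()
    score.checkboxes = cb
    return score


def _item_9(item, m, cfg, side):
    h = cfg.heuristics
    mid = m["hip_flexion_at_midstance"]
    ext = m["hip_extension_terminal_stance_peak"]
    if mid > h.hip_neutral_by_midstance_deg or ext > h.hip_extension_marked_deg:
        return _mk(item, "default", "abnormal_throughout")
    if ext >= h.hip_extension_reached_deg:
        return _mk(item, "default", "normal")
    return _mk(item, "default", "reduced_terminal_extension")


def _item_11(item, m, cfg, side):
    x = m["knee_flexion_at_initial_contact"]
    if x >= 0:
        return _classify_generic(item, item.branch("A"), m)
    mm = dict(m)
    mm["knee_hyperextension_at_initial_contact"] = -x
    return _classify_generic(item, item.branch("B"), mm)


def _item_12(item, m, cfg, side):
    mn = m["knee_flexion_loading_response_min"]
    if mn < 0:
        mm = dict(m)
        mm["knee_hyperextension_loading_response"] = -mn
        return _classify_generic(item, item.branch("B"), mm)
    return _classify_generic(item, item.branch("A"), m)


def _item_13(item, m, cfg, side):
    h = cfg.heuristics
    x = m["knee_flexion_midstance"]
    mn = m["knee_flexion_midstance_min"]
    early = m["knee_flexion_early_midstance_max"]
    vel = m["knee_extension_velocity_midstance_max"]
    v_unc = h.uncontrolled_extension_multiple * h.template_peak_extension_velocity_dps
    v_snap = h.snapping_extension_multiple * h.template_peak_extension_velocity_dps
    if mn < -15:
        return _mk(item, "B", "severe_hyperextension")
    if mn < 0:
        return _mk(item, "B", "mild_hyperextension")
    if x >= 30:
        return _mk(item, "A", "severe_flexion")
    if 15 < x < 30:
        return _mk(item, "A", "moderate_flexion")
    # control-quality branch: position alone cannot distinguish a controlled
    # from an uncontrolled return to extension -- angular-velocity heuristic,
    # always flagged; observed mode is authoritative for branch C/D.
    if early >= 5 and x < 2:
        if vel > v_snap:
            return _mk(item, "C", "snapping_extension", flagged=True)
        if vel > v_unc:
            return _mk(item, "C", "uncontrolled_extension", flagged=True)
    if 5 <= mn <= 15:
        return _mk(item, "A", "persistent_mild_flexion")
    if early < 5:
        return _mk(item, "B", "extended_not_hyperextended")
    if x < 2 and early >= 5:
        return _mk(item, "C", "extends_to_neutral_late", flagged=True)
    if 0 <= x < 5:
        return _mk(item, "A", "normal")
    return _mk(item, "A", "persistent_mild_flexion", flagged=True)


def _item_14(item, m, cfg, side):
    h = cfg.heuristics
    p = m["knee_flexion_preswing_max"]
    e = m["knee_flexion_at_toe_off"]
    if p <= h.knee_full_extension_deg:
        return _mk(item, "default", "full_extension_throughout")
    if 35 <= p <= 45:
        if p - e > h.knee_then_extends_drop_deg:
            return _mk(item, "default", "flexes_then_extends")
        return _mk(item, "default", "normal")
    return _mk(item, "default", "reduced_or_excess_flexion")


def _item_15(item, m, cfg, side):
    band = cfg.heuristics.point_anchor_band_deg
    hc = bool(m["heel_contact_present"])
    ic = m["ankle_dorsiflexion_at_initial_contact"]
    emin = m["ankle_dorsiflexion_early_stance_min"]
    lmax = m["ankle_dorsiflexion_late_stance_max"]
    mid = m["ankle_dorsiflexion_at_midstance"]
    smin = m["ankle_dorsiflexion_stance_min"]
    smax = m["ankle_dorsiflexion_stance_max"]
    if smin > 20:
        return _mk(item, "B", "excessive_df_throughout")
    if 15 <= mid <= 20:
        return _mk(item, "B", "moderate_df_midstance")
    if lmax > 10 + band and -5 <= ic <= 5:
        return _mk(item, "B", "df_after_midstance")
    if not hc:
        return _mk(item, "A", "no_heel_contact")
    if emin < -15:
        return _mk(item, "A", "vaulting")
    if ic < -5 and smax < -2:
        return _mk(item, "A", "foot_flat_pf_to_heel_off")
    if ic < -5 and lmax < 5:
        return _mk(item, "A", "foot_flat_then_pf")
    if -5 <= ic <= 5 and lmax < 0:
        return _mk(item, "A", "pf_after_midstance")
    if -5 <= ic <= 5 and -15 <= emin <= band and 10 - band <= lmax <= 10 + band:
        return _mk(item, "A", "normal")
    # abnormal but unlisted (e.g. foot-flat contact with recovered push-off)
    if ic < -5:
        return _mk(item, "A", "foot_flat_then_pf", flagged=True)
    return _mk(item, "A", "pf_after_midstance", flagged=True)


def _item_16(item, m, cfg, side):
    thr = cfg.heuristics.inversion_excessive_deg
    ic = m["ankle_inversion_at_initial_contact"]
    mid = m["ankle_inversion_at_midstance"]
    smin = m["ankle_inversion_stance_min"]
    if smin > thr:
        return _mk(item, "default", "inversion_throughout")
    if ic > thr and mid > thr:
        return _mk(item, "default", "inversion_contact_midstance")
    if ic > thr:
        return _mk(item, "default", "inversion_at_contact")
    if mid > thr:  # unlisted pattern: midstance-only inversion
        return _mk(item, "default", "inversion_at_contact", flagged=True)
    return _mk(item, "default", "normal")


def _item_18(item, m, cfg, side):
    h = cfg.heuristics
    if m["toe_angle_stance_min"] <= h.toe_clawing_deg:
        return _mk(item, "default", "clawing")
    if m["toe_angle_stance_max"] > h.toe_excessive_extension_deg:
        return _mk(item, "default", "excessive_extension")
    return _mk(item, "default", "normal")


def _item_24(item, m, cfg, side):
    h = cfg.heuristics
    p = m["hip_flexion_swing_max"]
    i0 = m["hip_flexion_at_toe_off"]
    a = m["hip_abduction_swing_dev"]
    abd_thr = h.hip_abduction_abnormal_deg
    if p > 38:
        return _mk(item, "default", "excessive_flexion")
    if p <= 10:
        return _mk(item, "default", "minimal_flexion")
    if p < 30:
        if a >= abd_thr:
            return _mk(item, "default", "circumduction")
        if a <= -abd_thr:
            return _mk(item, "default", "scissoring")
        return _mk(item, "default", "reduced_peak")
    if p >= 32:
        if a >= abd_thr:  # unlisted: frontal-plane deviation at normal peak
            return _mk(item, "default", "circumduction", flagged=True)
        if a <= -abd_thr:
            return _mk(item, "default", "scissoring", flagged=True)
        if i0 > h.hip_swing_begin_flexed_deg:
            return _mk(item, "default", "flexed_start_normal_peak")
        return _mk(item, "default", "normal")
    # the (30, 32] gap between the reduced-peak level and the normal band
    return _mk(item, "default", "reduced_peak", flagged=True)


def _item_26(item, m, cfg, side):
    mm = dict(m)
    mm.setdefault("knee_flexion_cycle_max", m["knee_flexion_initial_swing_max"])
    return _classify_generic(item, item.branches[0], mm)


def _item_28(item, m, cfg, side):
    h = cfg.heuristics
    ms = m["knee_flexion_midswing_max"]
    ts = m["knee_flexion_terminal_swing_min"]
    if ms >= h.knee_flexed_position_deg:
        if ts <= h.knee_terminal_extension_deg:
            return _mk(item, "default", "normal")
        return _mk(item, "default", "remains_flexed")
    return _mk(item, "default", "remains_extended")


def _item_29(item, m, cfg, side):
    h = cfg.heuristics
    mid = m["ankle_dorsiflexion_midswing"]
    term = m["ankle_dorsiflexion_terminal_swing_max"]
    if mid >= -h.ankle_neutral_band_deg:
        if term >= h.ankle_terminal_df_deg:
            return _mk(item, "default", "normal")
        return _mk(item, "default", "no_terminal_dorsiflexion")
    return _mk(item, "default", "plantarflexed_throughout")


def _item_31(item, m, cfg, side):
    h = cfg.heuristics
    t = m["toe_angle_midswing"]
    if t <= h.toe_clawing_deg:
        return _mk(item, "default", "clawing")
    if t < 0:
        return _mk(item, "default", "inadequate_extension")
    return _mk(item, "default", "normal")


_PATTERN: dict[int, Callable] = {
    1: _item_1,
    3: _item_3,
    4: _item_4,
    5: lambda it, m, c, s: _trunk_dynamic(it, m, c, s, "trunk_sagittal_stance_dev", True),
    6: lambda it, m, c, s: _trunk_dynamic(it, m, c, s, "trunk_coronal_stance_dev", False),
    9: _item_9,
    11: _item_11,
    12: _item_12,
    13: _item_13,
    14: _item_14,
    15: _item_15,
    16: _item_16,
    18: _item_18,
    19: lambda it, m, c, s: _trunk_dynamic(it, m, c, s, "trunk_sagittal_swing_dev", True),
    20: lambda it, m, c, s: _trunk_dynamic(it, m, c, s, "trunk_coronal_swing_dev", False),
    24: _item_24,
    26: _item_26,
    28: _item_28,
    29: _item_29,
    31: _item_31,
}

#: items whose levels are interval predicates on one measurement, eligible
#: for the ordinal-monotonicity property (grid) test
MONOTONE_ITEMS = (2, 5, 6, 7, 8, 17, 19, 20, 21, 26, 27)


def classify(item: ItemDefinition, measurements: dict,
             config: EngineConfig = DEFAULT_CONFIG,
             side: str = "right") -> ItemScore:
    fn = _PATTERN.get(item.id)
    if fn is not None:
        return fn(item, measurements, config, side)
    return _classify_generic(item, item.branches[0], measurements)
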