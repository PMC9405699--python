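"""Rubric measurements read from one gait cycle.

Every item's threshold predicate consumes a named scalar measurement read at
the item's temporal event (value at an event instant, or an extremum over a
named phase window).  This module holds that window arithmetic once, so the
kinematic pipeline (sampling a recorded cycle) and the simulator's analytic
oracle (sampling the deformed normative template) agree by construction on
*where* each value is read; they differ only in where the samples come from.

A cycle is addressed in percent of gait cycle: initial contact at 0, toe-off
at the detected/true percentage ``toe_off_pct``, next initial contact at
100.  Swing sub-phases (initial/mid/terminal thirds) are relative to the
actual swing window; midstance, heel-rise and the terminal-swing window are
the standard phase anchors from the engine configuration.
"""
from __future__ import annotations

from typing import Callable, Mapping

import numpy as np

from .config import DEFAULT_CONFIG, EngineConfig

#: channels consumed per measurement-group; used to decide which items are
#: scoreable from the channels a recording actually provides
CHANNEL_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "shoulder_flexion": ("shoulder_static_offset", "shoulder_excursion"),
    "elbow_flexion": ("elbow_flexion_mean",),
    "trunk_sagittal": ("trunk_sagittal_static", "trunk_sagittal_stance_dev",
                       "trunk_sagittal_swing_dev"),
    "trunk_coronal": ("trunk_coronal_static", "trunk_coronal_stance_dev",
                      "trunk_coronal_swing_dev"),
    "pelvis_lateral_displacement": ("weight_shift_mm",),
    "pelvic_obliquity": ("pelvic_drop_contralateral", "pelvic_hike_swing_max"),
    "pelvic_tilt": ("pelvic_tilt_dev",),
    "pelvic_rotation": ("pelvic_rotation_swing_excursion",),
    "hip_flexion": ("hip_flexion_at_initial_contact", "hip_flexion_at_midstance",
                    "hip_extension_terminal_stance_peak", "hip_flexion_at_toe_off",
                    "hip_flexion_swing_max"),
    "hip_abduction": ("hip_abduction_swing_dev",),
    "hip_rotation": ("hip_rotation_stance_dev", "hip_rotation_swing_dev"),
    "knee_flexion": ("knee_flexion_at_initial_contact",
                     "knee_flexion_loading_response_max",
                     "knee_flexion_loading_response_min",
                     "knee_flexion_midstance", "knee_flexion_midstance_min",
                     "knee_flexion_early_midstance_max",
                     "knee_extension_velocity_midstance_max",
                     "knee_flexion_preswing_max", "knee_flexion_at_toe_off",
                     "knee_flexion_initial_swing_max", "knee_flexion_midswing_max",
                     "knee_flexion_terminal_swing_min", "knee_flexion_cycle_max"),
    "ankle_dorsiflexion": ("ankle_dorsiflexion_at_initial_contact",
                           "ankle_dorsiflexion_early_stance_min",
                           "ankle_dorsiflexion_late_stance_max",
                           "ankle_dorsiflexion_at_midstance",
                           "ankle_dorsiflexion_stance_min",
                           "ankle_dorsiflexion_stance_max",
                           "ankle_plantarflexion_at_toe_off",
                           "ankle_dorsiflexion_midswing",
                           "ankle_dorsiflexion_terminal_swing_max"),
    "ankle_inversion": ("ankle_inversion_at_initial_contact",
                        "ankle_inversion_at_midstance",
                        "ankle_inversion_stance_min", "ankle_inversion_swing_max"),
    "toe_angle": ("toe_angle_stance_max", "toe_angle_stance_min",
                  "toe_angle_midswing"),
}

Sampler = Callable[[str, np.ndarray], np.ndarray]

_GRID_STEP = 0.25


def _signed_extremum(values: np.ndarray) -> float:
    """Signed value of largest magnitude."""
    return float(values[np.argmax(np.abs(values))])


def compute_cycle_measurements(
    sample: Sampler,
    channels: set[str],
    toe_off_pct: float,
    heel_contact_present: bool,
    cycle_duration_s: float,
    config: EngineConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Read every rubric measurement available from ``channels``.

    ``sample(channel, phases)`` returns channel values at percent-of-cycle
    phases in [0, 100].  Returns a flat name -> value mapping (plus the
    ``heel_contact_present`` flag and bookkeeping entries ``toe_off_pct``
    and ``cycle_duration_s``).
    """
    ev = config.events
    T = float(toe_off_pct)
    g = np.arange(0.0, 100.0 + _GRID_STEP / 2, _GRID_STEP)

    def win(lo: float, hi: float, lo_open: bool = True) -> np.ndarray:
        m = (g > lo) if lo_open else (g >= lo)
        return m & (g <= hi)

    stance = win(0.0, T, lo_open=False)
    swing = win(T, 100.0)
    sw = 100.0 - T
    midswing_instant = T + sw / 2.0
    initial_swing = win(T, T + sw / 3.0)
    midswing_win = win(T + sw / 3.0, T + 2.0 * sw / 3.0)
    terminal_swing = win(ev.terminal_swing_start, 100.0)
    m: dict[str, float] = {
        "heel_contact_present": float(bool(heel_contact_present)),
        "toe_off_pct": T,
        "cycle_duration_s": float(cycle_duration_s),
    }

    def at(ch: str, p: float) -> float:
        return float(sample(ch, np.array([p]))[0])

    if "shoulder_flexion" in channels:
        v = sample("shoulder_flexion", g)
        m["shoulder_static_offset"] = _signed_extremum(v[[np.argmin(np.abs(v))]])
        m["shoulder_excursion"] = float(v.max() - v.min())
    if "elbow_flexion" in channels:
        m["elbow_flexion_mean"] = float(sample("elbow_flexion", g).mean())

    for ch, prefix in (("trunk_sagittal", "trunk_sagittal"),
                       ("trunk_coronal", "trunk_coronal")):
        if ch in channels:
            v = sample(ch, g)
            static = float(v[np.argmin(np.abs(v))])
            m[f"{prefix}_static"] = static
            m[f"{prefix}_stance_dev"] = _signed_extremum(v[stance] - static)
            m[f"{prefix}_swing_dev"] = _signed_extremum(v[swing] - static)

    if "pelvis_lateral_displacement" in channels:
        m["weight_shift_mm"] = float(sample("pelvis_lateral_displacement", g)[stance].max())
    if "pelvic_obliquity" in channels:
        v = sample("pelvic_obliquity", g)
        lo, hi = ev.midstance_window
        m["pelvic_drop_contralateral"] = float(v[win(lo, hi)].max())
        m["pelvic_hike_swing_max"] = float(v[swing].max())
    if "pelvic_tilt" in channels:
        m["pelvic_tilt_dev"] = _signed_extremum(sample("pelvic_tilt", g))
    if "pelvic_rotation" in channels:
        v = sample("pelvic_rotation", g)[swing]
        m["pelvic_rotation_swing_excursion"] = float(v.max() - v.min())

    if "hip_flexion" in channels:
        v = sample("hip_flexion", g)
        m["hip_flexion_at_initial_contact"] = at("hip_flexion", 0.0)
        m["hip_flexion_at_midstance"] = at("hip_flexion", ev.midstance)
        m["hip_extension_terminal_stance_peak"] = float(-v[win(ev.heel_rise, T)].min())
        m["hip_flexion_at_toe_off"] = at("hip_flexion", T)
        m["hip_flexion_swing_max"] = float(v[swing].max())
    if "hip_abduction" in channels:
        m["hip_abduction_swing_dev"] = _signed_extremum(sample("hip_abduction", g)[swing])
    if "hip_rotation" in channels:
        v = sample("hip_rotation", g)
        m["hip_rotation_stance_dev"] = _signed_extremum(v[stance])
        m["hip_rotation_swing_dev"] = _signed_extremum(v[swing])

    if "knee_flexion" in channels:
        v = sample("knee_flexion", g)
        lr = win(0.0, ev.loading_response_end, lo_open=False)
        mid_lo, mid_hi = ev.midstance_window
        mid_win = win(mid_lo, mid_hi)
        early_mid = win(mid_lo, mid_lo + 10.0)
        m["knee_flexion_at_initial_contact"] = at("knee_flexion", 0.0)
        m["knee_flexion_loading_response_max"] = float(v[lr].max())
        m["knee_flexion_loading_response_min"] = float(v[lr].min())
        m["knee_flexion_midstance"] = at("knee_flexion", ev.midstance)
        m["knee_flexion_midstance_min"] = float(v[mid_win].min())
        m["knee_flexion_early_midstance_max"] = float(v[early_mid].max())
        dvdp = np.gradient(v, _GRID_STEP)  # deg per percent of cycle
        ext_vel = -dvdp * (100.0 / cycle_duration_s)  # deg/s, extension positive
        m["knee_extension_velocity_midstance_max"] = float(ext_vel[mid_win].max())
        m["knee_flexion_preswing_max"] = float(v[win(ev.heel_rise, T)].max())
        m["knee_flexion_at_toe_off"] = at("knee_flexion", T)
        m["knee_flexion_initial_swing_max"] = float(v[initial_swing].max())
        m["knee_flexion_midswing_max"] = float(v[midswing_win].max())
        m["knee_flexion_terminal_swing_min"] = float(v[terminal_swing].min())
        m["knee_flexion_cycle_max"] = float(v.max())

    if "ankle_dorsiflexion" in channels:
        v = sample("ankle_dorsiflexion", g)
        early = win(0.0, ev.midstance, lo_open=False)
        late = win(ev.midstance, T)
        m["ankle_dorsiflexion_at_initial_contact"] = at("ankle_dorsiflexion", 0.0)
        m["ankle_dorsiflexion_early_stance_min"] = float(v[early].min())
        m["ankle_dorsiflexion_late_stance_max"] = float(v[late].max())
        m["ankle_dorsiflexion_at_heel_rise"] = at("ankle_dorsiflexion", ev.heel_rise)
        m["ankle_dorsiflexion_at_midstance"] = at("ankle_dorsiflexion", ev.midstance)
        m["ankle_dorsiflexion_stance_min"] = float(v[stance].min())
        m["ankle_dorsiflexion_stance_max"] = float(v[stance].max())
        m["ankle_plantarflexion_at_toe_off"] = -at("ankle_dorsiflexion", T)
        m["ankle_dorsiflexion_midswing"] = at("ankle_dorsiflexion", midswing_instant)
        m["ankle_dorsiflexion_terminal_swing_max"] = float(v[terminal_swing].max())
    if "ankle_inversion" in channels:
        v = sample("ankle_inversion", g)
        m["ankle_inversion_at_initial_contact"] = at("ankle_inversion", 0.0)
        m["ankle_inversion_at_midstance"] = at("ankle_inversion", ev.midstance)
        m["ankle_inversion_stance_min"] = float(v[stance].min())
        m["ankle_inversion_swing_max"] = float(v[swing].max())
    if "toe_angle" in channels:
        v = sample("toe_angle", g)
        m["toe_angle_stance_max"] = float(v[stance].max())
        m["toe_angle_stance_min"] = float(v[stance].min())
        m["toe_angle_midswing"] = at("toe_angle", midswing_instant)
    return m


def item_inputs_from_measurements(measurements: Mapping[str, float]):
    """Split a flat measurement mapping into per-item measured-mode inputs;
    items whose required measurements are absent are returned separately
    with the missing names (they become excluded-as-unscoreable)."""
    from .rubric import ItemInput, load_rubric

    inputs, unscoreable = [], {}
    extras = {26: ("knee_flexion_cycle_max",)}
    for item in load_rubric():
        missing = [n for n in item.required_inputs if n not in measurements]
        if missing:
            unscoreable[item.id] = missing
            continue
        names = list(item.required_inputs) + [n for n in extras.get(item.id, ())
                                              if n in measurements]
        inputs.append(ItemInput(
            item_id=item.id, mode="measured",
            measurements={n: measurements[n] for n in names}))
    return inputs, unscoreable
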