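"""Tunable constants of the scoring engine and kinematic pipeline.

The instrument's printed thresholds are fixed (they live in the packaged
rubric and are not user-configurable); what is collected here are the
conventions the instrument leaves open: realized bands around printed
single-point normal anchors, phase-percentage anchors for events a rater
identifies by eye, contact-detection thresholds, and the heuristics used
where a printed level describes movement quality rather than a threshold.
All angles are degrees, displacements/heights millimetres, times seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class EventConventions:
    """Phase anchors (percent of gait cycle) for events not observable from
    foot contacts alone.  Initial contact is 0 by definition; toe-off is
    detected from the toe-height channel.  The 14%-of-cycle knee anchor of
    the midstance item is honoured by the normative template."""

    loading_response_end: float = 10.0
    midstance: float = 30.0          # instant used for "at midstance" reads
    midstance_window: tuple[float, float] = (10.0, 40.0)
    heel_rise: float = 40.0          # terminal-stance onset
    terminal_swing_start: float = 87.0  # last 13% of the cycle


@dataclass(frozen=True)
class ContactDetection:
    """Foot-contact detection on heel/toe height channels."""

    threshold_mm: float = 5.0        # contact when < bout minimum + threshold
    hysteresis_mm: float = 2.0       # leave contact only above threshold + this
    refine_mm: float = 2.0           # event refined to this floor-proximity crossing
    min_dwell_s: float = 0.05        # sustained-state guard against chatter
    heel_contact_abs_mm: float = 10.0  # heel considered to strike if it comes this close to the floor


@dataclass(frozen=True)
class MeasuredModeHeuristics:
    """Constants used by measured-mode item classifiers where the instrument
    prints a quality description or a single normal value without a band."""

    # band half-widths around printed point anchors
    point_anchor_band_deg: float = 3.0    # e.g. "10 deg dorsiflexion at heel off"
    trunk_static_abnormal_deg: float = 5.0
    shoulder_static_abnormal_deg: float = 10.0
    # arm swing: reduced when excursion falls below this fraction of normal
    arm_swing_fraction: float = 0.5
    template_shoulder_excursion_deg: float = 30.0
    # weight shift: printed normal ~25 mm; "excessive" cutoff is 2x normal
    excessive_weight_shift_mm: float = 50.0
    # excessive inversion/supination (no printed degree value)
    inversion_excessive_deg: float = 10.0
    # hip-extension item: terminal-stance extension counted as reached
    hip_extension_reached_deg: float = 12.0
    hip_extension_marked_deg: float = 35.0
    hip_neutral_by_midstance_deg: float = 5.0
    # knee terminal-stance item
    knee_full_extension_deg: float = 8.0
    knee_then_extends_drop_deg: float = 10.0
    # knee terminal-swing item: "flexed position" / "full extension"
    knee_flexed_position_deg: float = 15.0
    knee_terminal_extension_deg: float = 8.0
    # ankle swing item
    ankle_neutral_band_deg: float = 2.0
    ankle_terminal_df_deg: float = 2.0
    # midstance control-quality branch: uncontrolled extension when peak
    # extension velocity exceeds this multiple of the normal template's peak
    uncontrolled_extension_multiple: float = 2.0
    snapping_extension_multiple: float = 3.5
    template_peak_extension_velocity_dps: float = 60.0
    # hip swing item
    hip_swing_begin_flexed_deg: float = 10.0
    hip_abduction_abnormal_deg: float = 5.0
    # toe items
    toe_excessive_extension_deg: float = 25.0
    toe_clawing_deg: float = -10.0


@dataclass(frozen=True)
class EngineConfig:
    events: EventConventions = field(default_factory=EventConventions)
    contact: ContactDetection = field(default_factory=ContactDetection)
    heuristics: MeasuredModeHeuristics = field(default_factory=MeasuredModeHeuristics)

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = EngineConfig()
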