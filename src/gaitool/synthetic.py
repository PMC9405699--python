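"""Synthetic gait generator with known ground-truth item scores.

A normative template encodes, per channel, a piecewise-cubic curve over
percent gait cycle through the instrument's printed normal anchors (knee 4
deg flexion at initial contact rising to 15 deg at 14% of the cycle,
35-45 deg in pre-swing, 60 deg at midswing; hip 30 deg flexion at contact to
20 deg extension in terminal stance, ~35 deg swing peak; ankle neutral at
contact, 10 deg plantarflexion before midstance, 10 deg dorsiflexion at
heel-off, 10 deg plantarflexion at push-off; pelvic rotation -5 to +5 deg;
~25 mm weight shift; and so on).  Anchors the instrument does not print
(shoulder excursion, foot-clearance heights, hiking/inversion magnitudes)
use conventional normal-gait values and are plain constants below.

Named deviations deform the template's anchors; a profile is a set of
deviations with magnitudes.  ``generate`` tiles the (deformed) template over
``n_steps`` assessed-side steps with cadence/amplitude ramps on the first
and last two steps -- so the middle-step administration rule is observable
-- adds optional Gaussian noise, and emits the trajectories together with
ground-truth events and the expected score sheet.  ``expected_scores``
applies the rubric predicates to the deformed template analytically (dense
phase grid, true toe-off percentage, no tiling/sampling/event detection) and
is the oracle the full pipeline is tested against.

Ground-truth event convention: initial contact and toe-off are where the
template's contact channels cross 2 mm floor proximity; the template phase
axis is shifted once so initial contact sits exactly at phase 0.  Detector
and generator therefore share one event definition.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

from .config import DEFAULT_CONFIG, EngineConfig
from .kinematics import CycleEvents, GaitEvents, JointTrajectories
from .measurements import compute_cycle_measurements, item_inputs_from_measurements
from .rubric import ItemScore, ScoreSheet, SheetMetadata, score_sheet

Anchors = dict[str, list[tuple[float, float]]]

#: normative per-channel anchors (percent cycle, value); deg unless noted mm
BASE_TEMPLATE: Anchors = {
    "knee_flexion": [(0, 4), (14, 15), (30, 4), (40, 6), (50, 22), (60, 42),
                     (80, 60), (94, 10), (100, 4)],
    "hip_flexion": [(0, 30), (30, 0), (50, -20), (60, 0), (85, 35), (100, 30)],
    "hip_abduction": [(0, 0), (100, 0)],
    "hip_rotation": [(0, 0), (100, 0)],
    "ankle_dorsiflexion": [(0, 0), (12, -10), (40, 10), (60, -15), (80, 0),
                           (95, 4), (100, 0)],
    "ankle_inversion": [(0, 4), (25, -3), (60, -2), (80, 0), (100, 4)],
    "trunk_sagittal": [(0, 0), (100, 0)],
    "trunk_coronal": [(0, 0), (100, 0)],
    "pelvic_obliquity": [(0, 0), (15, 3), (40, 2), (60, 0), (80, -3), (100, 0)],
    "pelvic_tilt": [(0, 0), (100, 0)],
    "pelvic_rotation": [(0, 5), (45, -5), (60, -5), (100, 5)],
    "shoulder_flexion": [(0, 18), (50, -12), (100, 18)],
    "elbow_flexion": [(0, 10), (100, 10)],
    "pelvis_lateral_displacement": [(0, 0), (30, 25), (60, 0), (80, -25), (100, 0)],  # mm
    "heel_height": [(0, 0), (38, 0), (48, 40), (62, 130), (80, 170), (94, 24), (100, 0)],  # mm
    "toe_height": [(0, 14), (8, 0), (56, 0), (64, 16), (78, 100), (90, 45), (100, 14)],  # mm
    "toe_angle": [(0, 5), (100, 5)],
}

_CONTACT_CHANNELS = ("heel_height", "toe_height")


class UnknownDeviationError(ValueError):
    pass


@dataclass(frozen=True)
class AbnormalityProfile:
    """Named set of deviations with magnitudes.  Expected item scores are
    always *derived* from the rubric predicates via ``expected_scores``,
    never entered by hand."""

    name: str
    deviations: dict[str, dict] = field(default_factory=dict)
    description: str = ""
    boundary_adjacent: bool = False  # sits near a printed threshold on purpose


@dataclass(frozen=True)
class SimulationConfig:
    n_steps: int = 8            # assessed-side steps (one initial contact each)
    cadence: float = 55.0       # assessed-side steps per minute (~1.09 s cycles)
    sample_rate: float = 100.0  # Hz
    noise_sd: float = 0.0       # deg on angles, mm on displacement/height channels
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")


# ---------------------------------------------------------------------------
# deviation vocabulary

def _dev_swing_knee_flexion_peak(a: Anchors, magnitude: float = 20.0):
    a["knee_flexion"] = [(0, 4), (14, 15), (30, 4), (40, 6), (50, 22),
                         (60, min(42.0, magnitude + 5)), (80, magnitude),
                         (94, min(10.0, 0.4 * magnitude)), (100, 4)]


def _dev_stiff_knee(a: Anchors):
    a["knee_flexion"] = [(0, 2), (100, 2)]


def _dev_very_stiff_swing(a: Anchors):
    a["knee_flexion"] = [(0, 4), (14, 15), (30, 4), (40, 5), (50, 6), (60, 8),
                         (80, 8), (94, 5), (100, 4)]


def _dev_knee_hyperextension_midstance(a: Anchors, magnitude: float = 10.0):
    a["knee_flexion"] = [(0, 4), (14, 8), (25, -magnitude), (35, -magnitude),
                         (42, 4), (50, 22), (60, 42), (80, 60), (94, 10), (100, 4)]


def _dev_knee_flexion_contracture_ic(a: Anchors, magnitude: float = 20.0):
    a["knee_flexion"] = [(0, magnitude), (14, max(magnitude, 18.0)), (30, 4),
                         (40, 6), (50, 22), (60, 42), (80, 60),
                         (94, max(12.0, magnitude)), (100, magnitude)]


def _dev_knee_hyperextension_ic(a: Anchors, magnitude: float = 10.0):
    a["knee_flexion"] = [(0, -magnitude), (10, 0), (14, 12), (30, 4), (40, 6),
                         (50, 22), (60, 42), (80, 60), (94, 6), (100, -magnitude)]


def _dev_persistent_midstance_flexion(a: Anchors):
    a["knee_flexion"] = [(0, 6), (14, 12), (30, 8), (40, 9), (50, 24), (60, 42),
                         (80, 60), (94, 10), (100, 6)]


def _dev_abrupt_knee_extension(a: Anchors):
    a["knee_flexion"] = [(0, 4), (14, 15), (22, 1), (32, 1), (40, 6), (50, 22),
                         (60, 42), (80, 60), (94, 10), (100, 4)]


def _dev_preswing_collapse(a: Anchors):
    a["knee_flexion"] = [(0, 4), (14, 15), (30, 4), (40, 38), (48, 40), (55, 15),
                         (60, 12), (75, 30), (80, 32), (94, 8), (100, 4)]


def _dev_crouch_gait(a: Anchors):
    a["knee_flexion"] = [(0, 32), (10, 34), (30, 30), (40, 32), (50, 35),
                         (60, 45), (80, 60), (94, 30), (100, 32)]


def _dev_equinus(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, -25), (12, -28), (40, -20), (60, -25),
                               (80, -25), (95, -25), (100, -25)]
    a["heel_height"] = [(0, 30), (38, 30), (48, 70), (62, 160), (80, 190),
                        (94, 50), (100, 30)]
    a["toe_height"] = [(0, 0), (56, 0), (64, 16), (78, 100), (90, 45),
                       (96, 4), (100, 0)]


def _dev_foot_drop(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, -8), (12, -12), (40, 10), (60, -15),
                               (80, -12), (95, -10), (100, -8)]


def _dev_vaulting(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (10, -20), (25, -20), (40, 8), (60, -15),
                               (80, 0), (95, 4), (100, 0)]


def _dev_late_plantarflexion(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (12, -10), (30, -2), (40, -6), (55, -8),
                               (60, -12), (80, 0), (95, 4), (100, 0)]


def _dev_foot_flat_plantarflexed(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, -12), (12, -14), (40, -8), (60, -16),
                               (80, -6), (95, -8), (100, -12)]


def _dev_no_push_off(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (12, -8), (40, 3), (55, 3), (60, 2),
                               (80, 0), (95, 4), (100, 0)]


def _dev_weak_push_off(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (12, -10), (40, 8), (55, 2), (60, -5),
                               (80, 0), (95, 4), (100, 0)]


def _dev_excessive_dorsiflexion(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 22), (12, 21), (40, 25), (58, 22), (80, 23),
                               (95, 23), (100, 22)]


def _dev_dorsiflexion_midstance(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (12, -3), (30, 17), (40, 17), (50, 16),
                               (60, -10), (80, 0), (95, 4), (100, 0)]


def _dev_dorsiflexion_after_midstance(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (12, -8), (35, 10), (45, 18), (55, 16),
                               (60, -14), (80, 0), (95, 4), (100, 0)]


def _dev_no_terminal_dorsiflexion(a: Anchors):
    a["ankle_dorsiflexion"] = [(0, 0), (12, -10), (40, 10), (60, -15), (80, 0),
                               (90, -1), (100, 0)]


def _dev_trunk_lateral_lean(a: Anchors, magnitude: float = 35.0):
    a["trunk_coronal"] = [(0, 0), (20, magnitude), (45, magnitude), (65, 0), (100, 0)]


def _dev_trunk_dynamic_flexion(a: Anchors, magnitude: float = 20.0):
    a["trunk_sagittal"] = [(0, 0), (25, magnitude), (50, magnitude), (70, 3), (100, 0)]


def _dev_trunk_static_lean(a: Anchors, sagittal: float = 0.0, coronal: float = 0.0):
    if sagittal:
        a["trunk_sagittal"] = [(0, sagittal), (100, sagittal)]
    if coronal:
        a["trunk_coronal"] = [(0, coronal), (100, coronal)]


def _dev_trendelenburg(a: Anchors, magnitude: float = 7.0):
    a["pelvic_obliquity"] = [(0, 0), (15, magnitude), (40, magnitude - 1),
                             (60, 0), (80, -3), (100, 0)]


def _dev_hip_hiking(a: Anchors, magnitude: float = 12.0):
    a["pelvic_obliquity"] = [(0, 0), (15, 3), (40, 2), (60, 0), (70, magnitude),
                             (85, magnitude), (95, 1), (100, 0)]


def _dev_weight_shift(a: Anchors, magnitude: float = 10.0):
    a["pelvis_lateral_displacement"] = [(0, 0), (30, magnitude), (60, 0),
                                        (80, -min(magnitude, 25.0)), (100, 0)]


def _dev_reduced_hip_extension(a: Anchors, residual: float = 4.0):
    a["hip_flexion"] = [(0, 30), (30, 0), (50, -residual), (60, 0), (85, 35), (100, 30)]


def _dev_hip_flexed_throughout(a: Anchors):
    a["hip_flexion"] = [(0, 30), (30, 14), (50, 8), (60, 10), (85, 35), (100, 30)]


def _dev_hip_swing_reduced(a: Anchors, peak: float = 22.0, abduction: float = 0.0):
    a["hip_flexion"] = [(0, peak), (30, 0), (50, -18), (60, 0), (85, peak), (100, peak)]
    if abduction:
        a["hip_abduction"] = [(0, 0), (60, abduction / 10), (75, abduction),
                              (88, abduction), (97, abduction / 10), (100, 0)]


def _dev_hip_minimal_flexion(a: Anchors):
    a["hip_flexion"] = [(0, 8), (30, 0), (50, -16), (60, 2), (85, 8), (100, 8)]


def _dev_excessive_hip_flexion(a: Anchors):
    a["hip_flexion"] = [(0, 30), (30, 2), (50, -18), (60, 5), (85, 45), (100, 30)]


def _dev_hip_rotation_offset(a: Anchors, magnitude: float = 10.0):
    a["hip_rotation"] = [(0, magnitude), (100, magnitude)]


def _dev_pelvic_tilt_offset(a: Anchors, magnitude: float = 12.0):
    a["pelvic_tilt"] = [(0, magnitude), (100, magnitude)]


def _dev_pelvic_rotation_amplitude(a: Anchors, amplitude: float = 1.5):
    a["pelvic_rotation"] = [(0, amplitude), (45, -amplitude), (60, -amplitude),
                            (100, amplitude)]


def _dev_ankle_inversion_pattern(a: Anchors, kind: str = "throughout"):
    patterns = {
        "ic": [(0, 15), (10, 8), (25, -3), (60, -2), (80, 4), (100, 15)],
        "ic_mid": [(0, 15), (30, 15), (45, 5), (60, -2), (80, 4), (100, 15)],
        "throughout": [(0, 15), (100, 15)],
        "swing_only": [(0, 4), (25, -3), (55, -2), (70, 14), (90, 14), (100, 4)],
    }
    if kind not in patterns:
        raise UnknownDeviationError(f"unknown inversion pattern {kind!r}")
    a["ankle_inversion"] = patterns[kind]


def _dev_toe_posture(a: Anchors, offset: float = -15.0):
    a["toe_angle"] = [(0, offset), (100, offset)]


def _dev_elbow_flexion_offset(a: Anchors, mean: float = 100.0):
    a["elbow_flexion"] = [(0, mean), (100, mean)]


def _dev_arm_swing(a: Anchors, excursion: float = 9.0, offset: float = 0.0):
    a["shoulder_flexion"] = [(0, offset + excursion / 2), (50, offset - excursion / 2),
                             (100, offset + excursion / 2)]


#: deviation name -> (anchor transform, item ids it affects)
DEVIATIONS: dict[str, tuple[Callable, tuple[int, ...]]] = {
    "swing_knee_flexion_peak": (_dev_swing_knee_flexion_peak, (14, 26, 27)),
    "stiff_knee": (_dev_stiff_knee, (13, 14, 26, 27, 28)),
    "very_stiff_swing": (_dev_very_stiff_swing, (14, 26, 27, 28)),
    "knee_hyperextension_midstance": (_dev_knee_hyperextension_midstance, (13,)),
    "knee_flexion_contracture_ic": (_dev_knee_flexion_contracture_ic, (11, 12, 28)),
    "knee_hyperextension_ic": (_dev_knee_hyperextension_ic, (11, 12)),
    "persistent_midstance_flexion": (_dev_persistent_midstance_flexion, (11, 13)),
    "abrupt_knee_extension": (_dev_abrupt_knee_extension, (13,)),
    "preswing_collapse": (_dev_preswing_collapse, (14, 26, 27)),
    "crouch_gait": (_dev_crouch_gait, (11, 12, 13, 28)),
    "equinus": (_dev_equinus, (15, 29)),
    "foot_drop": (_dev_foot_drop, (15, 29)),
    "vaulting": (_dev_vaulting, (15,)),
    "late_plantarflexion": (_dev_late_plantarflexion, (15,)),
    "foot_flat_plantarflexed": (_dev_foot_flat_plantarflexed, (15, 17, 29)),
    "no_push_off": (_dev_no_push_off, (15, 17)),
    "weak_push_off": (_dev_weak_push_off, (17,)),
    "excessive_dorsiflexion": (_dev_excessive_dorsiflexion, (15, 17)),
    "dorsiflexion_midstance": (_dev_dorsiflexion_midstance, (15, 17)),
    "dorsiflexion_after_midstance": (_dev_dorsiflexion_after_midstance, (15,)),
    "no_terminal_dorsiflexion": (_dev_no_terminal_dorsiflexion, (29,)),
    "trunk_lateral_lean": (_dev_trunk_lateral_lean, (6, 20)),
    "trunk_dynamic_flexion": (_dev_trunk_dynamic_flexion, (5, 19)),
    "trunk_static_lean": (_dev_trunk_static_lean, (4,)),
    "trendelenburg": (_dev_trendelenburg, (8,)),
    "hip_hiking": (_dev_hip_hiking, (21,)),
    "weight_shift": (_dev_weight_shift, (7,)),
    "reduced_hip_extension": (_dev_reduced_hip_extension, (9,)),
    "hip_flexed_throughout": (_dev_hip_flexed_throughout, (9,)),
    "hip_swing_reduced": (_dev_hip_swing_reduced, (24,)),
    "hip_minimal_flexion": (_dev_hip_minimal_flexion, (24,)),
    "excessive_hip_flexion": (_dev_excessive_hip_flexion, (24,)),
    "hip_rotation_offset": (_dev_hip_rotation_offset, (10, 25)),
    "pelvic_tilt_offset": (_dev_pelvic_tilt_offset, (22,)),
    "pelvic_rotation_amplitude": (_dev_pelvic_rotation_amplitude, (23,)),
    "ankle_inversion_pattern": (_dev_ankle_inversion_pattern, (16, 30)),
    "toe_posture": (_dev_toe_posture, (18, 31)),
    "elbow_flexion_offset": (_dev_elbow_flexion_offset, (2,)),
    "arm_swing": (_dev_arm_swing, (1, 3)),
}


def apply_deviations(profile: AbnormalityProfile) -> Anchors:
    anchors = copy.deepcopy(BASE_TEMPLATE)
    for name, params in profile.deviations.items():
        if name not in DEVIATIONS:
            raise UnknownDeviationError(f"unknown deviation {name!r}")
        DEVIATIONS[name][0](anchors, **(params or {}))
    return anchors


# ---------------------------------------------------------------------------
# template evaluation

class Template:
    """Periodic piecewise-cubic (shape-preserving) template over percent
    cycle, phase-shifted so initial contact sits at phase 0."""

    def __init__(self, anchors: Anchors,
                 config: EngineConfig = DEFAULT_CONFIG):
        self._fns: dict[str, PchipInterpolator] = {}
        for ch, pts in anchors.items():
            ph = np.array([p for p, _ in pts], float)
            va = np.array([v for _, v in pts], float)
            if ph[0] != 0.0 or ph[-1] != 100.0:
                raise ValueError(f"channel {ch}: anchors must span 0..100")
            # periodic continuation for smooth boundary derivatives
            core_ph, core_va = ph[:-1], va[:-1]
            ext_ph = np.concatenate([core_ph - 100.0, core_ph, core_ph + 100.0,
                                     [200.0]])
            ext_va = np.concatenate([core_va, core_va, core_va, [va[0]]])
            self._fns[ch] = PchipInterpolator(ext_ph, ext_va)
        self._shift = 0.0
        self._refine = config.contact.refine_mm
        self._shift = self._compute_shift()
        self.toe_off_pct = self._compute_toe_off()
        self.heel_contact = self._compute_heel_contact(config)

    @property
    def channels(self) -> set[str]:
        return set(self._fns)

    def sample(self, channel: str, phases) -> np.ndarray:
        p = (np.asarray(phases, float) + self._shift) % 100.0
        return self._fns[channel](p)

    def _compute_shift(self) -> float:
        g = np.arange(0.0, 100.0, 0.02)
        c = np.minimum(self.sample("heel_height", g), self.sample("toe_height", g))
        level = float(c.min()) + self._refine
        down = np.nonzero((c[:-1] > level) & (c[1:] <= level))[0]
        if len(down) == 0:
            return 0.0
        i = down[-1]
        frac = (c[i] - level) / (c[i] - c[i + 1])
        return float(g[i] + frac * (g[i + 1] - g[i]))

    def _compute_toe_off(self) -> float:
        g = np.arange(0.0, 100.0, 0.02)
        toe = self.sample("toe_height", g)
        level = float(toe.min()) + self._refine
        up = np.nonzero((toe[:-1] <= level) & (toe[1:] > level)
                        & (g[:-1] > 20.0) & (g[:-1] < 95.0))[0]
        if len(up) == 0:
            return 60.0
        i = up[0]
        frac = (level - toe[i]) / (toe[i + 1] - toe[i])
        return float(g[i] + frac * (g[i + 1] - g[i]))

    def _compute_heel_contact(self, config: EngineConfig) -> bool:
        g = np.concatenate([np.arange(98.0, 100.0, 0.05),
                            np.arange(0.0, 15.0, 0.05)])
        return bool(self.sample("heel_height", g).min()
                    < config.contact.heel_contact_abs_mm)


# ---------------------------------------------------------------------------
# oracle

def expected_observation(profile: AbnormalityProfile,
                         cadence: float = 55.0,
                         config: EngineConfig = DEFAULT_CONFIG) -> dict[str, float]:
    """Rubric measurements of the deformed template, computed analytically."""
    tpl = Template(apply_deviations(profile), config)
    return compute_cycle_measurements(
        tpl.sample, tpl.channels, tpl.toe_off_pct, tpl.heel_contact,
        60.0 / cadence, config)


def expected_scores(profile: AbnormalityProfile,
                    cadence: float = 55.0,
                    config: EngineConfig = DEFAULT_CONFIG) -> dict[int, ItemScore]:
    """Analytic application of the rubric predicates to the deformed
    template -- the brute-force oracle for the full measured pipeline."""
    m = expected_observation(profile, cadence, config)
    inputs, unscoreable = item_inputs_from_measurements(m)
    if unscoreable:
        raise RuntimeError(f"template incomplete for items {sorted(unscoreable)}")
    from .rubric import rubric_by_id, score_item
    by_id = rubric_by_id()
    return {inp.item_id: score_item(by_id[inp.item_id], inp, config)
            for inp in inputs}


def expected_sheet(profile: AbnormalityProfile, context=None,
                   cadence: float = 55.0,
                   config: EngineConfig = DEFAULT_CONFIG) -> ScoreSheet:
    m = expected_observation(profile, cadence, config)
    inputs, _ = item_inputs_from_measurements(m)
    md = SheetMetadata(name=f"synthetic:{profile.name}", cycle_id="template")
    return score_sheet(inputs, context, config, metadata=md)


# ---------------------------------------------------------------------------
# time-series generation

_RAMP_TEMPO = (1.15, 1.07)   # first/last two steps are slower ...
_RAMP_AMPLITUDE = (0.8, 0.9)  # ... and smaller: scoring them would mis-score items


@dataclass
class SimulationResult:
    trajectories: JointTrajectories
    events: GaitEvents           # ground-truth contacts/toe-offs
    expected: ScoreSheet         # oracle-derived expected score sheet
    measurements: dict[str, float]  # oracle template measurements
    profile: AbnormalityProfile
    config: SimulationConfig


def generate(profile: AbnormalityProfile,
             config: SimulationConfig = SimulationConfig(),
             engine: EngineConfig = DEFAULT_CONFIG) -> SimulationResult:
    """Simulate one walking bout.  Reproducible: identical profile + config
    give bit-identical trajectories."""
    tpl = Template(apply_deviations(profile), engine)
    n = config.n_steps
    base = 60.0 / config.cadence
    tempo = np.ones(n)
    amp = np.ones(n)
    for d, (tf, af) in enumerate(zip(_RAMP_TEMPO, _RAMP_AMPLITUDE)):
        if d < n:
            tempo[d] = max(tempo[d], tf)
            amp[d] = min(amp[d], af)
            tempo[n - 1 - d] = max(tempo[n - 1 - d], tf)
            amp[n - 1 - d] = min(amp[n - 1 - d], af)
    durations = base * tempo
    pre_roll = 0.30 * durations[0]
    contacts = pre_roll + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    total = contacts[-1] + 0.45 * durations[-1]
    t = np.arange(0.0, total, 1.0 / config.sample_rate)

    seg = np.searchsorted(contacts, t, side="right") - 1
    phase = np.empty_like(t)
    amp_t = np.empty_like(t)
    pre = seg < 0
    phase[pre] = 100.0 - (contacts[0] - t[pre]) / durations[0] * 100.0
    amp_t[pre] = amp[0]
    for k in range(n):
        mask = seg == k
        phase[mask] = (t[mask] - contacts[k]) / durations[k] * 100.0
        amp_t[mask] = amp[k]
    phase = np.clip(phase, 0.0, None) % 100.0

    rng = np.random.default_rng(config.seed)
    channels = {}
    for ch in sorted(tpl.channels):
        v = amp_t * tpl.sample(ch, phase)
        if config.noise_sd > 0:
            v = v + rng.normal(0.0, config.noise_sd, size=v.shape)
        channels[ch] = v
    traj = JointTrajectories(time=t, channels=channels,
                             sample_rate=config.sample_rate)

    ev = engine.events
    cycles = []
    for k in range(n - 1):
        ic, nxt = float(contacts[k]), float(contacts[k + 1])
        dur = nxt - ic
        to = ic + tpl.toe_off_pct / 100.0 * dur
        pct = {"initial_contact": 0.0,
               "loading_response_end": ev.loading_response_end,
               "midstance": ev.midstance, "heel_rise": ev.heel_rise,
               "toe_off": tpl.toe_off_pct,
               "terminal_swing": ev.terminal_swing_start}
        pct["midswing"] = (tpl.toe_off_pct + 100.0) / 2.0
        times = {name: ic + p / 100.0 * dur for name, p in pct.items()}
        cycles.append(CycleEvents(step=k + 1, initial_contact=ic,
                                  next_contact=nxt, toe_off=to,
                                  events_s=times, events_pct=pct))
    events = GaitEvents(step_count=n, contact_times=[float(c) for c in contacts],
                        cycles=cycles)
    m = compute_cycle_measurements(tpl.sample, tpl.channels, tpl.toe_off_pct,
                                   tpl.heel_contact, base, engine)
    return SimulationResult(trajectories=traj, events=events,
                            expected=expected_sheet(profile, cadence=config.cadence,
                                                    config=engine),
                            measurements=m, profile=profile, config=config)


# ---------------------------------------------------------------------------
# packaged profile suite

def load_profiles() -> dict[str, AbnormalityProfile]:
    text = resources.files("gaitool.data").joinpath("profiles.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for p in raw["profiles"]:
        prof = AbnormalityProfile(
            name=p["name"], deviations=p.get("deviations") or {},
            description=p.get("description", ""),
            boundary_adjacent=bool(p.get("boundary_adjacent", False)))
        for dev in prof.deviations:
            if dev not in DEVIATIONS:
                raise UnknownDeviationError(
                    f"profile {prof.name!r}: unknown deviation {dev!r}")
        out[prof.name] = prof
    return out


def load_observed_fixtures() -> list[dict]:
    """Observed-mode fixtures for items unreachable from kinematics alone
    (shoulder sub-descriptors, midstance control-quality branches C/D)."""
    text = resources.files("gaitool.data").joinpath("profiles.yaml").read_text()
    return yaml.safe_load(text).get("observed_fixtures", [])
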