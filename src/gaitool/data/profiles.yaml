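# Packaged abnormality-profile suite for the synthetic gait generator.
# Each profile names deviations from the deviation vocabulary; the expected
# item scores are always derived at run time by applying the rubric
# predicates to the deformed template (synthetic.expected_scores) -- they
# are deliberately not written down here a second time.
profiles:
- name: normal
  description: Noise-free normative template; scores 0 on every item.
- name: equinus
  description: Toe-walking - no heel contact, plantarflexed throughout.
  deviations: {equinus: {}}
- name: foot_drop
  description: Swing-phase plantarflexion with forefoot-first contact.
  deviations: {foot_drop: {}}
- name: reduced_swing_knee_flexion
  description: Stiff-knee swing, midswing peak ~20 deg.
  deviations: {swing_knee_flexion_peak: {magnitude: 20}}
- name: stiff_knee
  description: Knee effectively never flexes (held at ~2 deg).
  deviations: {stiff_knee: {}}
- name: very_stiff_swing
  description: Swing knee flexion peaks below 15 deg although the knee moves.
  deviations: {very_stiff_swing: {}}
- name: knee_hyperextension_midstance
  description: 10 deg midstance hyperextension (back-knee thrust).
  deviations: {knee_hyperextension_midstance: {magnitude: 10}}
- name: severe_knee_hyperextension_midstance
  deviations: {knee_hyperextension_midstance: {magnitude: 20}}
- name: knee_flexion_contracture
  description: 20 deg flexion contracture visible at initial contact.
  deviations: {knee_flexion_contracture_ic: {magnitude: 20}}
- name: knee_hyperextension_initial_contact
  deviations: {knee_hyperextension_ic: {magnitude: 10}}
- name: persistent_midstance_flexion
  description: Mild flexion held through midstance, never reaching neutral.
  deviations: {persistent_midstance_flexion: {}}
- name: abrupt_knee_extension
  description: Early midstance flexion snapped back into extension.
  deviations: {abrupt_knee_extension: {}}
  boundary_adjacent: true
- name: preswing_collapse
  description: Normal pre-swing flexion peak that collapses before toe-off.
  deviations: {preswing_collapse: {}}
- name: crouch_gait
  description: Knee held above 30 deg flexion through stance.
  deviations: {crouch_gait: {}}
- name: trunk_lateral_lean_35
  description: Dynamic 35 deg stance-phase lateral trunk lean.
  deviations: {trunk_lateral_lean: {magnitude: 35}}
- name: trunk_dynamic_flexion
  deviations: {trunk_dynamic_flexion: {magnitude: 20}}
- name: severe_trunk_flexion
  deviations: {trunk_dynamic_flexion: {magnitude: 34}}
- name: static_lateral_trunk_lean
  deviations: {trunk_static_lean: {coronal: 10}}
- name: static_trunk_flexion
  deviations: {trunk_static_lean: {sagittal: 10}}
- name: static_combined_trunk_lean
  deviations: {trunk_static_lean: {sagittal: 10, coronal: 10}}
- name: trendelenburg_mild
  deviations: {trendelenburg: {magnitude: 7}}
- name: trendelenburg_severe
  deviations: {trendelenburg: {magnitude: 14}}
- name: hip_hiking_mild
  deviations: {hip_hiking: {magnitude: 5}}
- name: hip_hiking_moderate
  deviations: {hip_hiking: {magnitude: 12}}
- name: circumduction
  description: Reduced hip flexion peak advanced through abduction.
  deviations: {hip_swing_reduced: {peak: 22, abduction: 10}}
- name: scissoring
  description: Reduced hip flexion peak with adduction across midline.
  deviations: {hip_swing_reduced: {peak: 22, abduction: -10}}
- name: reduced_hip_flexion_peak
  deviations: {hip_swing_reduced: {peak: 22}}
- name: minimal_hip_flexion
  deviations: {hip_minimal_flexion: {}}
- name: excessive_hip_flexion
  deviations: {excessive_hip_flexion: {}}
- name: reduced_weight_shift
  deviations: {weight_shift: {magnitude: 10}}
- name: absent_weight_shift
  deviations: {weight_shift: {magnitude: 2}}
- name: excessive_weight_shift
  deviations: {weight_shift: {magnitude: 60}}
- name: reduced_hip_extension
  description: Neutral reached by midstance but terminal extension absent.
  deviations: {reduced_hip_extension: {residual: 4}}
- name: hip_flexed_throughout
  deviations: {hip_flexed_throughout: {}}
- name: no_push_off
  deviations: {no_push_off: {}}
- name: weak_push_off
  deviations: {weak_push_off: {}}
- name: excessive_dorsiflexion
  deviations: {excessive_dorsiflexion: {}}
- name: dorsiflexion_at_midstance
  deviations: {dorsiflexion_midstance: {}}
- name: dorsiflexion_after_midstance
  deviations: {dorsiflexion_after_midstance: {}}
- name: late_plantarflexion
  description: Normal heel strike, ankle drifting plantar after midstance.
  deviations: {late_plantarflexion: {}}
- name: foot_flat_plantarflexed
  description: Foot-flat contact with plantarflexion through to heel-off.
  deviations: {foot_flat_plantarflexed: {}}
- name: vaulting
  description: Excessive early-stance plantarflexion (swing-limb clearance).
  deviations: {vaulting: {}}
- name: no_terminal_dorsiflexion
  deviations: {no_terminal_dorsiflexion: {}}
- name: inversion_at_contact
  deviations: {ankle_inversion_pattern: {kind: ic}}
- name: inversion_contact_midstance
  deviations: {ankle_inversion_pattern: {kind: ic_mid}}
- name: inversion_throughout
  deviations: {ankle_inversion_pattern: {kind: throughout}}
- name: inversion_swing
  deviations: {ankle_inversion_pattern: {kind: swing_only}}
- name: toe_clawing
  deviations: {toe_posture: {offset: -15}}
- name: excessive_toe_extension
  deviations: {toe_posture: {offset: 30}}
- name: elbow_flexion_100
  deviations: {elbow_flexion_offset: {mean: 100}}
- name: elbow_flexion_60
  deviations: {elbow_flexion_offset: {mean: 60}}
- name: reduced_arm_swing
  deviations: {arm_swing: {excursion: 9}}
- name: elevated_shoulder
  description: Static shoulder elevation with near-absent arm swing.
  deviations: {arm_swing: {excursion: 8, offset: 25}}
- name: internal_hip_rotation
  deviations: {hip_rotation_offset: {magnitude: 10}}
- name: external_hip_rotation
  deviations: {hip_rotation_offset: {magnitude: -10}}
- name: anterior_pelvic_tilt
  deviations: {pelvic_tilt_offset: {magnitude: 12}}
- name: posterior_pelvic_tilt
  deviations: {pelvic_tilt_offset: {magnitude: -12}}
- name: reduced_pelvic_rotation
  deviations: {pelvic_rotation_amplitude: {amplitude: 1.5}}
- name: absent_pelvic_rotation
  deviations: {pelvic_rotation_amplitude: {amplitude: 0.2}}
- name: excessive_pelvic_rotation
  deviations: {pelvic_rotation_amplitude: {amplitude: 10}}

# Items (or branches) unreachable from kinematics alone: shoulder
# sub-descriptors and the midstance control-quality branches C/D are a
# rater's judgement, exercised through observed-mode fixtures.
observed_fixtures:
- {item: 1, branch: default, code: abnormal_position, checkboxes: [depressed, retracted], expected_score: 1}
- {item: 1, branch: default, code: abnormal_position, checkboxes: [elevated], expected_score: 1}
- {item: 13, branch: C, code: snapping_extension, checkboxes: [], expected_score: 3}
- {item: 13, branch: D, code: late_controlled_flexion, checkboxes: [], expected_score: 1}
- {item: 13, branch: D, code: buckles, checkboxes: [], expected_score: 3}
- {item: 7, branch: default, code: excessive, checkboxes: [], expected_score: 2}
- {item: 22, branch: default, code: posterior_tilt, checkboxes: [], expected_score: 1}
- {item: 4, branch: default, code: combined_malalignment, checkboxes: [flexion, left], expected_score: 3}
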