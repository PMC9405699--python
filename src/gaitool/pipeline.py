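"""Measured-mode end-to-end pipeline: trajectories -> events -> validated
middle step -> measurements -> scored + adjusted sheet."""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .adjustments import ContextFlags
from .config import DEFAULT_CONFIG, EngineConfig
from .kinematics import (GaitCycleObservation, GaitEvents, JointTrajectories,
                         detect_events, extract_observation,
                         select_scoring_cycle, validate_recording)
from .measurements import item_inputs_from_measurements
from .rubric import ScoreSheet, SheetMetadata, score_sheet

log = logging.getLogger("gaitool")


@dataclass
class PipelineResult:
    sheet: ScoreSheet
    observation: GaitCycleObservation
    events: GaitEvents
    step: int
    eligible_steps: list[int]


def score_trajectories(traj: JointTrajectories,
                       context: Optional[ContextFlags] = None,
                       side: str = "right",
                       config: EngineConfig = DEFAULT_CONFIG,
                       events: Optional[GaitEvents] = None,
                       metadata: Optional[SheetMetadata] = None,
                       step: Optional[int] = None) -> PipelineResult:
    """Run detect -> validate -> select -> extract -> score -> adjust.

    ``events`` bypasses detection (events-override input); ``step`` forces a
    specific cycle (it must still be an eligible middle step unless the
    caller passes one explicitly for diagnostic use)."""
    context = context or ContextFlags(side=side)
    if events is None:
        events = detect_events(traj, side, config)
    eligible = validate_recording(events)
    if step is None:
        step = select_scoring_cycle(eligible)
    log.info("scoring step %d of %d (eligible middle steps: %s)",
             step, events.step_count, eligible)
    obs = extract_observation(traj, events, step, side, config)
    inputs, unscoreable = item_inputs_from_measurements(obs.measurements)
    exclusions = {iid: "unscoreable - channel(s) missing for: " + ", ".join(names)
                  for iid, names in unscoreable.items()}
    for iid, reason in exclusions.items():
        log.warning("item %d excluded: %s", iid, reason)
    md = metadata or SheetMetadata()
    md.cycle_id = md.cycle_id or f"step-{step}"
    sheet = score_sheet(inputs, context, config, side=side, metadata=md,
                        exclusions=exclusions)
    for sc in sheet.item_scores:
        if sc.adjusted:
            log.info("item %d adjusted to %d (%s)", sc.item_id, sc.score,
                     sc.adjustment_reason)
        if sc.flagged_for_review:
            log.info("item %d flagged for review (%s)", sc.item_id,
                     sc.descriptor_code)
    return PipelineResult(sheet=sheet, observation=obs, events=events,
                          step=step, eligible_steps=eligible)
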