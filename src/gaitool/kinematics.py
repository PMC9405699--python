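"""Gait-event detection and measurement extraction from joint-angle and
displacement time series.

Sign conventions: flexion, dorsiflexion, inversion, anterior pelvic tilt and
trunk lean toward the assessed side are positive; knee hyperextension is
negative knee flexion.  Angles in degrees, displacements and foot heights in
millimetres (heights above the floor), time in seconds.

Initial contact is detected on the foot-contact signal (pointwise minimum of
heel and toe height) as the refined floor-proximity crossing; toe-off as the
toe channel leaving the floor.  Midstance, heel-rise, midswing and terminal
swing are placed at standard phase percentages of each detected cycle (the
percentages live in the engine configuration).  A recording is valid for
scoring only if it contains at least six steps, and the first two and last
two steps are never scored: they carry the acceleration/deceleration of the
bout.  All items are scored on one selected middle step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .config import DEFAULT_CONFIG, EngineConfig
from .measurements import CHANNEL_DEPENDENCIES, compute_cycle_measurements

MIN_STEPS = 6
EDGE_STEPS_EXCLUDED = 2  # first/last steps unusable (acceleration/deceleration)

KNOWN_CHANNELS = tuple(CHANNEL_DEPENDENCIES) + ("heel_height", "toe_height",
                                                "foot_anterior_position")


class RecordingError(ValueError):
    """Unusable recording (format, sampling, or too few steps)."""


@dataclass
class JointTrajectories:
    """Uniformly sampled named channels for one walking bout."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    sample_rate: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise RecordingError("time vector must be 1-D with at least 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise RecordingError("time must be strictly increasing")
        if t[-1] - t[0] < 2.0:
            raise RecordingError("recording shorter than 2 s")
        for name, v in self.channels.items():
            if len(v) != len(t):
                raise RecordingError(f"channel {name!r} length mismatch")

    def channel(self, name: str, side: Optional[str] = None) -> Optional[np.ndarray]:
        if side and f"{name}_{side}" in self.channels:
            return self.channels[f"{name}_{side}"]
        return self.channels.get(name)

    def present_channels(self, side: Optional[str] = None) -> set[str]:
        out = set()
        for name in KNOWN_CHANNELS:
            if self.channel(name, side) is not None:
                out.add(name)
        return out


@dataclass
class CycleEvents:
    """Temporal landmarks of one gait cycle of the assessed side."""

    step: int                 # 1-based index of the initial contact
    initial_contact: float    # s
    next_contact: float       # s
    toe_off: float            # s
    events_s: dict[str, float] = field(default_factory=dict)
    events_pct: dict[str, float] = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.next_contact - self.initial_contact

    @property
    def toe_off_pct(self) -> float:
        return 100.0 * (self.toe_off - self.initial_contact) / self.duration


@dataclass
class GaitEvents:
    step_count: int
    contact_times: list[float]
    cycles: list[CycleEvents]

    def cycle_for_step(self, step: int) -> CycleEvents:
        for c in self.cycles:
            if c.step == step:
                return c
        raise KeyError(f"no complete cycle starting at step {step}")


@dataclass
class GaitCycleObservation:
    """Flat mapping of measurement name -> value for one scored cycle, each
    tagged (via ``event_times``) with the event time it was read at."""

    step: int
    measurements: dict[str, float]
    event_times: dict[str, float]
    channels_present: set[str]
    unscoreable_items: dict[int, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CSV I/O

def read_trajectories_csv(path) -> JointTrajectories:
    """Read a wide CSV: first column time (s), remaining columns named
    channels; an optional second header row gives units.  Sampling must be
    uniform (linear-interpolation resampling tolerates < 1% jitter)."""
    df = pd.read_csv(path)
    if df.empty or df.shape[1] < 2:
        raise RecordingError(f"{path}: empty or single-column trajectory file")
    # optional units row: first data row entirely non-numeric
    first = df.iloc[0]
    if all(isinstance(x, str) and not _is_number(x) for x in first):
        df = df.iloc[1:].reset_index(drop=True)
    tcol = df.columns[0]
    if tcol.strip().lower() not in ("time", "t", "time_s"):
        raise RecordingError(f"{path}: first column must be the time column")
    try:
        df = df.astype(float)
    except ValueError as e:
        raise RecordingError(f"{path}: non-numeric cell in trajectory data ({e})")
    t = df[tcol].to_numpy()
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise RecordingError(f"{path}: time column not strictly increasing")
    dt = np.diff(t)
    jitter = (dt.max() - dt.min()) / np.median(dt)
    tu = t
    if jitter > 1e-6:
        if jitter > 0.01:
            raise RecordingError(f"{path}: sampling jitter {jitter:.1%} exceeds 1%")
        tu = np.linspace(t[0], t[-1], len(t))
    channels = {}
    for col in df.columns[1:]:
        base = col.rsplit("_left", 1)[0].rsplit("_right", 1)[0]
        if base not in KNOWN_CHANNELS:
            warnings.warn(f"unknown channel name {col!r}; it will be ignored "
                          f"by the scoring pipeline", stacklevel=2)
        v = df[col].to_numpy()
        channels[col] = np.interp(tu, t, v) if tu is not t else v
    return JointTrajectories(time=tu, channels=channels,
                             sample_rate=1.0 / float(np.median(np.diff(tu))))


def read_events_csv(path, config: EngineConfig = DEFAULT_CONFIG) -> GaitEvents:
    """Read an events-override CSV (columns: step, event, time_s) -- e.g. the
    generator's ground-truth events file -- bypassing contact detection.
    Requires an initial_contact per step; toe_off defaults to 60% of the
    cycle when absent; the remaining phase events are placed at their
    standard percentages."""
    df = pd.read_csv(path)
    need = {"step", "event", "time_s"}
    if not need.issubset(df.columns):
        raise RecordingError(f"{path}: events file needs columns {sorted(need)}")
    ics: dict[int, float] = {}
    toes: dict[int, float] = {}
    for _, row in df.iterrows():
        if row["event"] == "initial_contact":
            ics[int(row["step"])] = float(row["time_s"])
        elif row["event"] == "toe_off":
            toes[int(row["step"])] = float(row["time_s"])
    if len(ics) < 2:
        raise RecordingError(f"{path}: fewer than 2 initial contacts")
    steps = sorted(ics)
    ev = config.events
    cycles = []
    for k, nxt in zip(steps, steps[1:]):
        ic, nc = ics[k], ics[nxt]
        dur = nc - ic
        if dur <= 0:
            raise RecordingError(f"{path}: contacts not increasing at step {k}")
        to = toes.get(k, ic + 0.60 * dur)
        pct = {"initial_contact": 0.0,
               "loading_response_end": ev.loading_response_end,
               "midstance": ev.midstance, "heel_rise": ev.heel_rise,
               "toe_off": 100.0 * (to - ic) / dur,
               "terminal_swing": ev.terminal_swing_start}
        pct["midswing"] = (pct["toe_off"] + 100.0) / 2.0
        times = {name: ic + p / 100.0 * dur for name, p in pct.items()}
        cycles.append(CycleEvents(step=k, initial_contact=ic, next_contact=nc,
                                  toe_off=to, events_s=times, events_pct=pct))
    return GaitEvents(step_count=len(steps), contact_times=[ics[s] for s in steps],
                      cycles=cycles)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_trajectories_csv(traj: JointTrajectories, path) -> None:
    data = {"time": traj.time} | {k: v for k, v in traj.channels.items()}
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# event detection

def _smooth(v: np.ndarray, fs: float, window_s: float = 0.11) -> np.ndarray:
    """Savitzky-Golay smoothing (order 3): attenuates measurement noise
    while reproducing smooth joint curves near-exactly."""
    window = int(round(window_s * fs))
    window = max(5, window + (window + 1) % 2)  # odd, >= 5
    if len(v) <= window:
        return v
    return savgol_filter(v, window_length=window, polyorder=3)


def _smooth_contact(v: np.ndarray, fs: float) -> np.ndarray:
    # short window: a long one rounds the touchdown corner of the height
    # channels and biases the refined contact crossing by several ms
    return _smooth(v, fs, window_s=0.05)


def _floor_level(sig: np.ndarray) -> float:
    """Robust floor estimate: the bout minimum is an extreme statistic and
    collapses under noise; the 10th percentile sits inside the on-floor
    sample cluster (the foot is on the floor for a large fraction of every
    cycle) and equals the minimum on noise-free data."""
    return float(np.percentile(sig, 10.0))


def _contact_runs(sig: np.ndarray, fs: float, cfg: EngineConfig) -> list[tuple[int, int]]:
    """Sustained below-threshold runs (contacts) with hysteresis + dwell."""
    thr = _floor_level(sig) + cfg.contact.threshold_mm
    hi = thr + cfg.contact.hysteresis_mm
    dwell = max(1, int(round(cfg.contact.min_dwell_s * fs)))
    below = sig < thr
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(sig)
    while i < n:
        if below[i]:
            j = i
            while j < n:
                if sig[j] > hi:
                    # candidate exit: require sustained time above hi
                    k = j
                    while k < n and sig[k] > thr:
                        k += 1
                    if k - j >= dwell or k == n:
                        break
                    j = k
                else:
                    j += 1
            if j - i >= dwell:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _refine_crossing(t: np.ndarray, sig: np.ndarray, level: float,
                     start: int, stop: int, rising: bool) -> float:
    """Interpolated time where sig crosses `level` inside [start, stop)."""
    sl = sig[start:stop]
    if rising:
        idx = np.nonzero(sl > level)[0]
    else:
        idx = np.nonzero(sl <= level)[0]
    if len(idx) == 0:
        return float(t[start])
    i = start + idx[0]
    if i == 0:
        return float(t[0])
    v0, v1 = sig[i - 1], sig[i]
    if v1 == v0:
        return float(t[i])
    frac = (level - v0) / (v1 - v0)
    frac = min(max(frac, 0.0), 1.0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def detect_events(traj: JointTrajectories, side: str = "right",
                  config: EngineConfig = DEFAULT_CONFIG) -> GaitEvents:
    """Detect per-step initial contacts and toe-offs; derive the remaining
    phase events at their standard cycle percentages."""
    heel = traj.channel("heel_height", side)
    toe = traj.channel("toe_height", side)
    if heel is None and toe is None:
        raise RecordingError(
            "no gait cycle detected: heel_height/toe_height channel required")
    parts = [ _smooth_contact(np.asarray(c, float), traj.sample_rate)
              for c in (heel, toe) if c is not None ]
    contact_sig = parts[0] if len(parts) == 1 else np.minimum(*parts)
    if float(contact_sig.max() - contact_sig.min()) < config.contact.threshold_mm:
        raise RecordingError("no gait cycle detected: contact channel is flat")

    t = traj.time
    runs = _contact_runs(contact_sig, traj.sample_rate, config)
    if len(runs) < 2:
        raise RecordingError("no gait cycle detected: fewer than 2 foot contacts")
    level = _floor_level(contact_sig) + config.contact.refine_mm
    contacts = [
        _refine_crossing(t, contact_sig, level, max(0, i - 1), j, rising=False)
        for i, j in runs
    ]

    toe_s = _smooth_contact(np.asarray(toe, float), traj.sample_rate) if toe is not None else None
    ev = config.events
    cycles: list[CycleEvents] = []
    for k in range(len(contacts) - 1):
        ic, nxt = contacts[k], contacts[k + 1]
        dur = nxt - ic
        to = ic + 0.60 * dur  # fallback if no toe channel
        if toe_s is not None:
            lo = int(np.searchsorted(t, ic + 0.25 * dur))
            hi = int(np.searchsorted(t, ic + 0.95 * dur))
            if hi > lo:
                seg = toe_s[lo:hi]
                lvl = _floor_level(toe_s) + config.contact.refine_mm
                on_floor = np.nonzero(seg <= lvl)[0]
                if len(on_floor):
                    start = lo + on_floor[-1]
                    to = _refine_crossing(t, toe_s, lvl, start,
                                          min(len(t), start + int(traj.sample_rate)),
                                          rising=True)
        pct = {"initial_contact": 0.0,
               "loading_response_end": ev.loading_response_end,
               "midstance": ev.midstance,
               "heel_rise": ev.heel_rise,
               "toe_off": 100.0 * (to - ic) / dur,
               "terminal_swing": ev.terminal_swing_start}
        pct["midswing"] = (pct["toe_off"] + 100.0) / 2.0
        times = {name: ic + p / 100.0 * dur for name, p in pct.items()}
        order = ["initial_contact", "loading_response_end", "midstance",
                 "heel_rise", "toe_off", "midswing", "terminal_swing"]
        if any(times[a] >= times[b] for a, b in zip(order, order[1:])):
            continue  # degenerate cycle; not usable
        cycles.append(CycleEvents(step=k + 1, initial_contact=ic, next_contact=nxt,
                                  toe_off=to, events_s=times, events_pct=pct))
    return GaitEvents(step_count=len(contacts), contact_times=contacts, cycles=cycles)


def validate_recording(events: GaitEvents, min_steps: int = MIN_STEPS) -> list[int]:
    """Administration rule: >= 6 steps required; the first two and last two
    steps are excluded from scoring.  Returns eligible step indices."""
    n = events.step_count
    if n < min_steps:
        raise RecordingError(
            f"recording has {n} steps; a minimum of {min_steps} steps is required")
    eligible = [s for s in range(1 + EDGE_STEPS_EXCLUDED, n - EDGE_STEPS_EXCLUDED + 1)
                if any(c.step == s for c in events.cycles)]
    if not eligible:
        raise RecordingError("no eligible middle step with a complete gait cycle")
    return eligible


def select_scoring_cycle(eligible: list[int]) -> int:
    """The median eligible (middle) step; ties break to the earlier step."""
    if not eligible:
        raise RecordingError("no eligible steps")
    return sorted(eligible)[(len(eligible) - 1) // 2]


# ---------------------------------------------------------------------------
# measurement extraction

def extract_observation(traj: JointTrajectories, events: GaitEvents, step: int,
                        side: str = "right",
                        config: EngineConfig = DEFAULT_CONFIG) -> GaitCycleObservation:
    """Read every rubric measurement from the selected cycle at its named
    event; items whose channels are absent are reported as unscoreable."""
    cyc = events.cycle_for_step(step)
    t0, dur = cyc.initial_contact, cyc.duration
    present = traj.present_channels(side)
    smoothed = {name: _smooth(np.asarray(traj.channel(name, side), float),
                              traj.sample_rate)
                for name in present if traj.channel(name, side) is not None}

    def sample(name: str, phases: np.ndarray) -> np.ndarray:
        return np.interp(t0 + np.asarray(phases) / 100.0 * dur, traj.time,
                         smoothed[name])

    heel = smoothed.get("heel_height")
    if heel is not None:
        lo = int(np.searchsorted(traj.time, t0 - 0.02 * dur))
        hi = int(np.searchsorted(traj.time, t0 + 0.15 * dur))
        heel_contact = bool(heel[lo:hi].min() < config.contact.heel_contact_abs_mm)
    else:
        heel_contact = True  # unknown; item 15 will be unscoreable anyway

    meas_channels = {c for c in present if c in CHANNEL_DEPENDENCIES}
    m = compute_cycle_measurements(sample, meas_channels, cyc.toe_off_pct,
                                   heel_contact, dur, config)
    if heel is None:
        del m["heel_contact_present"]

    from .rubric import load_rubric
    unscoreable = {it.id: missing for it in load_rubric()
                   if (missing := [n for n in it.required_inputs if n not in m])}
    event_times = dict(cyc.events_s)
    return GaitCycleObservation(step=step, measurements=m, event_times=event_times,
                                channels_present=present,
                                unscoreable_items=unscoreable)
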