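"""Event detection, recording validation, cycle selection and extraction."""
import numpy as np
import pytest

from gaitool.kinematics import (JointTrajectories, RecordingError,
                                detect_events, extract_observation,
                                read_trajectories_csv, select_scoring_cycle,
                                validate_recording, write_trajectories_csv)
from gaitool.pipeline import score_trajectories
from gaitool.synthetic import SimulationConfig, generate


class TestEventDetection:
    def test_events_match_generator_truth_within_one_sample(self, normal_bout):
        ev = detect_events(normal_bout.trajectories)
        dt = 1.0 / normal_bout.trajectories.sample_rate
        assert ev.step_count == normal_bout.events.step_count
        for det, true in zip(ev.contact_times, normal_bout.events.contact_times):
            assert abs(det - true) <= dt
        for c in ev.cycles:
            true = normal_bout.events.cycle_for_step(c.step)
            assert abs(c.toe_off - true.toe_off) <= dt

    def test_event_ordering_and_percent_bounds(self, profiles):
        for name in ("normal", "equinus", "foot_drop", "stiff_knee"):
            res = generate(profiles[name], SimulationConfig(seed=3))
            for c in detect_events(res.trajectories).cycles:
                times = c.events_s
                order = ["initial_contact", "loading_response_end", "midstance",
                         "heel_rise", "toe_off", "midswing", "terminal_swing"]
                assert all(times[a] < times[b] for a, b in zip(order, order[1:]))
                assert all(0.0 <= p < 100.0 for p in c.events_pct.values())

    def test_flat_channels_error(self):
        t = np.arange(0, 3, 0.01)
        traj = JointTrajectories(t, {"heel_height": np.zeros_like(t),
                                     "toe_height": np.zeros_like(t)}, 100.0)
        with pytest.raises(RecordingError, match="no gait cycle"):
            detect_events(traj)

    def test_missing_contact_channels_error(self):
        t = np.arange(0, 3, 0.01)
        traj = JointTrajectories(t, {"knee_flexion": np.sin(t)}, 100.0)
        with pytest.raises(RecordingError, match="heel_height"):
            detect_events(traj)

    def test_reversed_time_rejected(self):
        t = np.arange(0, 3, 0.01)[::-1]
        with pytest.raises(RecordingError, match="increasing"):
            JointTrajectories(t, {"heel_height": np.zeros_like(t)}, 100.0)


class TestRecordingValidation:
    def test_five_steps_rejected(self, profiles):
        res = generate(profiles["normal"], SimulationConfig(n_steps=5))
        ev = detect_events(res.trajectories)
        with pytest.raises(RecordingError, match="5 steps"):
            validate_recording(ev)

    @pytest.mark.parametrize("n_steps,eligible", [
        (6, [3, 4]),
        (8, [3, 4, 5, 6]),
        (10, [3, 4, 5, 6, 7, 8]),
    ])
    def test_first_and_last_two_steps_excluded(self, profiles, n_steps, eligible):
        res = generate(profiles["normal"], SimulationConfig(n_steps=n_steps))
        ev = detect_events(res.trajectories)
        assert validate_recording(ev) == eligible

    @pytest.mark.parametrize("eligible,chosen", [
        ([3, 4], 3),           # tie -> earlier
        ([3, 4, 5, 6, 7, 8], 5),
        ([4], 4),
    ])
    def test_median_step_selection(self, eligible, chosen):
        assert select_scoring_cycle(eligible) == chosen


class TestExtraction:
    def test_recovers_template_measurements(self, normal_bout):
        ev = detect_events(normal_bout.trajectories)
        step = select_scoring_cycle(validate_recording(ev))
        obs = extract_observation(normal_bout.trajectories, ev, step)
        skip = {"toe_off_pct", "cycle_duration_s", "heel_contact_present"}
        for name, truth in normal_bout.measurements.items():
            if name in skip or name.endswith("velocity_midstance_max"):
                continue
            assert obs.measurements[name] == pytest.approx(truth, abs=0.5), name

    def test_equinus_heel_contact_absent(self, profiles):
        res = generate(profiles["equinus"], SimulationConfig(seed=5))
        ev = detect_events(res.trajectories)
        step = select_scoring_cycle(validate_recording(ev))
        obs = extract_observation(res.trajectories, ev, step)
        assert obs.measurements["heel_contact_present"] == 0.0

    def test_cycle_stability_noise_free(self, normal_bout):
        sheets = []
        ev = detect_events(normal_bout.trajectories)
        for step in validate_recording(ev):
            r = score_trajectories(normal_bout.trajectories, step=step)
            sheets.append([(s.item_id, s.score, s.descriptor_code)
                           for s in r.sheet.item_scores])
        assert all(s == sheets[0] for s in sheets)


class TestEventsOverride:
    def test_events_csv_bypasses_detection(self, normal_bout, tmp_path):
        from gaitool.kinematics import read_events_csv
        path = tmp_path / "events.csv"
        with path.open("w") as fh:
            fh.write("step,event,time_s\n")
            for c in normal_bout.events.cycles:
                for name, tt in c.events_s.items():
                    fh.write(f"{c.step},{name},{tt:.6f}\n")
            fh.write(f"{normal_bout.events.step_count},initial_contact,"
                     f"{normal_bout.events.contact_times[-1]:.6f}\n")
        ev = read_events_csv(path)
        assert ev.step_count == normal_bout.events.step_count
        via_override = score_trajectories(normal_bout.trajectories, events=ev).sheet
        via_detection = score_trajectories(normal_bout.trajectories).sheet
        assert [(s.item_id, s.score) for s in via_override.item_scores] == \
               [(s.item_id, s.score) for s in via_detection.item_scores]


class TestCsvIO:
    def test_round_trip(self, normal_bout, tmp_path):
        path = tmp_path / "traj.csv"
        write_trajectories_csv(normal_bout.trajectories, path)
        back = read_trajectories_csv(path)
        assert set(back.channels) == set(normal_bout.trajectories.channels)
        for name, v in normal_bout.trajectories.channels.items():
            assert np.allclose(back.channels[name], v, atol=1e-5)

    def test_knee_only_file_loads_and_restricts_scoring(self, normal_bout, tmp_path):
        traj = normal_bout.trajectories
        path = tmp_path / "knee.csv"
        sub = JointTrajectories(traj.time,
                                {"knee_flexion": traj.channels["knee_flexion"],
                                 "heel_height": traj.channels["heel_height"],
                                 "toe_height": traj.channels["toe_height"]},
                                traj.sample_rate)
        write_trajectories_csv(sub, path)
        result = score_trajectories(read_trajectories_csv(path))
        knee_items = {11, 12, 13, 14, 26, 27, 28}
        for sc in result.sheet.item_scores:
            if sc.item_id in knee_items:
                assert not sc.excluded and sc.score == 0
            elif sc.item_id not in (15,):  # 15 needs heel-contact + ankle
                assert sc.excluded or sc.item_id in knee_items
        assert result.sheet.max_possible < 62

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(Exception):
            read_trajectories_csv(p)

    def test_unknown_channel_warns(self, tmp_path, normal_bout):
        import pandas as pd
        t = normal_bout.trajectories.time[:400]
        pd.DataFrame({"time": t,
                      "heel_height": normal_bout.trajectories.channels["heel_height"][:400],
                      "mystery_channel": np.zeros(400)}).to_csv(
            tmp_path / "u.csv", index=False)
        with pytest.warns(UserWarning, match="mystery_channel"):
            read_trajectories_csv(tmp_path / "u.csv")
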