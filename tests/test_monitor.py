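"""Alarm state machine, end-to-end monitoring and rehabilitation sessions."""

import pytest

import posewatch as pw
from posewatch.monitor import (
    OBS_FALL,
    OBS_NO_FALL,
    OBS_NONE,
    OBS_STAND_UP,
    AlarmStage,
    MonitorConfig,
    MonitorState,
    manual_reset,
    step_fall_monitor,
)
from posewatch.synthetic import fall, hold, quick_sit, stand_up

CFG = MonitorConfig(safety_time=10.0, urgent_grace=5.0)


def state(stage, fall_start=None, t=0.0):
    return MonitorState(stage=stage, fall_start=fall_start, alarm_active=stage is AlarmStage.EMERGENCY, last_t=t)


class TestStateMachineTable:
    """Exhaustive (stage x observation) transitions at sub-threshold timing."""

    @pytest.mark.parametrize("obs", [OBS_FALL, OBS_NO_FALL, OBS_STAND_UP, OBS_NONE])
    @pytest.mark.parametrize("stage", list(AlarmStage))
    def test_transition_table(self, stage, obs):
        fall_start = 0.0 if stage in (AlarmStage.ABNORMAL, AlarmStage.URGENT) else None
        s0 = state(stage, fall_start)
        s1, events = step_fall_monitor(s0, obs, t=1.0, config=CFG)  # well within SafetyTime
        if stage is AlarmStage.NORMAL:
            expected = AlarmStage.ABNORMAL if obs == OBS_FALL else AlarmStage.NORMAL
        elif stage in (AlarmStage.ABNORMAL, AlarmStage.URGENT):
            expected = AlarmStage.NORMAL if obs == OBS_STAND_UP else stage
        else:  # Emergency is absorbing for every observation
            expected = AlarmStage.EMERGENCY
        assert s1.stage is expected
        kinds = [e.kind for e in events]
        assert "alarm_started" not in kinds  # never below the time thresholds
        if stage in (AlarmStage.ABNORMAL, AlarmStage.URGENT) and obs == OBS_STAND_UP:
            assert "alarm_discarded" in kinds

    def test_timer_starts_only_from_normal(self):
        s1, _ = step_fall_monitor(state(AlarmStage.NORMAL), OBS_FALL, 1.0, CFG)
        assert s1.fall_start == 1.0
        s2, _ = step_fall_monitor(s1, OBS_FALL, 4.0, CFG)
        assert s2.fall_start == 1.0  # continuous falls do not restart the episode


class TestEscalationTiming:
    def test_discard_before_safety_time(self):
        s, _ = step_fall_monitor(state(AlarmStage.NORMAL), OBS_FALL, 0.0, CFG)
        s, events = step_fall_monitor(s, OBS_STAND_UP, 2.0, CFG)
        assert s.stage is AlarmStage.NORMAL and s.fall_start is None
        assert [e.kind for e in events] == ["alarm_discarded", "stage_change"]

    def test_full_escalation_sequence(self):
        s, _ = step_fall_monitor(state(AlarmStage.NORMAL), OBS_FALL, 0.0, CFG)
        s, _ = step_fall_monitor(s, OBS_FALL, 9.9, CFG)
        assert s.stage is AlarmStage.ABNORMAL
        s, events = step_fall_monitor(s, OBS_FALL, 10.1, CFG)
        assert s.stage is AlarmStage.URGENT
        s, events = step_fall_monitor(s, OBS_NO_FALL, 15.1, CFG)
        assert s.stage is AlarmStage.EMERGENCY and s.alarm_active
        assert "alarm_started" in [e.kind for e in events]

    def test_no_observation_leaves_timer_running(self):
        s, _ = step_fall_monitor(state(AlarmStage.NORMAL), OBS_FALL, 0.0, CFG)
        for t in (5.0, 11.0, 16.0):
            s, events = step_fall_monitor(s, OBS_NONE, t, CFG)
        assert s.stage is AlarmStage.EMERGENCY

    def test_emergency_ignores_stand_up(self):
        s = state(AlarmStage.EMERGENCY, t=20.0)
        s1, events = step_fall_monitor(s, OBS_STAND_UP, 21.0, CFG)
        assert s1.stage is AlarmStage.EMERGENCY and not events

    def test_time_running_backwards_rejected(self):
        s = state(AlarmStage.NORMAL, t=5.0)
        with pytest.raises(ValueError, match="backwards"):
            step_fall_monitor(s, OBS_NO_FALL, 4.0, CFG)

    def test_unknown_observation_rejected(self):
        with pytest.raises(ValueError, match="observation"):
            step_fall_monitor(state(AlarmStage.NORMAL), "jump", 0.0, CFG)


class TestManualReset:
    def test_emergency_to_normal(self):
        s, events = manual_reset(state(AlarmStage.EMERGENCY, t=30.0))
        assert s.stage is AlarmStage.NORMAL and not s.alarm_active
        assert [e.kind for e in events] == ["reset"]

    def test_outside_emergency_is_warned_noop(self):
        with pytest.warns(UserWarning, match="ignored"):
            s, events = manual_reset(state(AlarmStage.NORMAL))
        assert s.stage is AlarmStage.NORMAL
        assert events[0].from_stage is events[0].to_stage

    def test_reset_then_fall_starts_fresh_cycle(self):
        s, _ = manual_reset(state(AlarmStage.EMERGENCY, t=30.0))
        s, _ = step_fall_monitor(s, OBS_FALL, 31.0, CFG)
        assert s.stage is AlarmStage.ABNORMAL and s.fall_start == 31.0


class TestRunMonitor:
    def test_empty_stream_yields_no_events(self, fall_bundle, lower_bundle):
        assert pw.run_monitor([], fall_bundle, lower_bundle) == []

    def test_scripted_fall_produces_exactly_one_alarm(
        self, subject, camera, calibration, fall_bundle, lower_bundle
    ):
        frames = pw.render_script(
            subject,
            pw.MotionScript((hold("standing", 1.0), fall(0.7, 20.0))),
            camera,
            seed=21,
            jitter_sigma=0.02,
        )
        events = pw.run_monitor(
            frames, fall_bundle, lower_bundle, MonitorConfig(), calibration=calibration
        )
        alarms = [e for e in events if e.kind == "alarm_started"]
        assert len(alarms) == 1
        # the alarm fires SafetyTime + grace after the first fall observation
        fall_obs_t = min(e.timestamp for e in events if e.to_stage is AlarmStage.ABNORMAL)
        assert alarms[0].timestamp - fall_obs_t == pytest.approx(15.0, abs=0.25)

    def test_quick_sit_confounder_raises_no_alarm(
        self, subject, camera, calibration, fall_bundle, lower_bundle
    ):
        frames = pw.render_script(
            subject,
            pw.MotionScript((hold("standing", 1.0), quick_sit(0.8, 18.0))),
            camera,
            seed=22,
            jitter_sigma=0.02,
        )
        events = pw.run_monitor(
            frames, fall_bundle, lower_bundle, MonitorConfig(), calibration=calibration
        )
        assert not [e for e in events if e.kind == "alarm_started"]

    def test_standing_back_up_discards_the_episode(
        self, subject, camera, calibration, fall_bundle, lower_bundle
    ):
        frames = pw.render_script(
            subject,
            pw.MotionScript(
                (hold("standing", 1.0), fall(0.7, 3.0), stand_up(1.0), hold("standing", 3.0))
            ),
            camera,
            seed=23,
            jitter_sigma=0.02,
        )
        events = pw.run_monitor(
            frames,
            fall_bundle,
            lower_bundle,
            MonitorConfig(safety_time=8.0, urgent_grace=4.0),
            calibration=calibration,
        )
        kinds = [e.kind for e in events]
        assert "alarm_discarded" in kinds and "alarm_started" not in kinds

    def test_identical_stream_and_config_reproduce_events(
        self, subject, camera, calibration, fall_bundle, lower_bundle
    ):
        frames = pw.render_script(
            subject,
            pw.MotionScript((hold("standing", 0.5), fall(0.6, 17.0))),
            camera,
            seed=24,
            jitter_sigma=0.02,
        )
        runs = [
            pw.run_monitor(frames, fall_bundle, lower_bundle, MonitorConfig(), calibration=calibration)
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
        ts = [e.timestamp for e in runs[0]]
        assert ts == sorted(ts)

    def test_alarm_hook_is_invoked(self, subject, camera, calibration, fall_bundle, lower_bundle):
        frames = pw.render_script(
            subject,
            pw.MotionScript((hold("standing", 0.5), fall(0.6, 17.0))),
            camera,
            seed=25,
            jitter_sigma=0.02,
        )
        seen = []
        pw.run_monitor(
            frames, fall_bundle, lower_bundle, MonitorConfig(),
            calibration=calibration, alarm_hook=seen.append,
        )
        assert len(seen) == 1 and seen[0].kind == "alarm_started"


def posture_stream(subject, camera, postures, seconds_each=2.0, fps=30.0):
    """Frames holding each posture exactly `seconds_each`, no transitions."""
    frames = []
    t = 0.0
    for name in postures:
        for _ in range(int(seconds_each * fps)):
            t += 1.0 / fps
            frames.append(
                pw.render_posture(subject, name, camera, jitter_sigma=0.01,
                                  seed=len(frames), timestamp=t)
            )
    return frames


class TestRehabSession:
    def test_all_postures_achieved_first_attempt(self, subject, camera, calibration, upper_bundle):
        plan = pw.RehabPlan(postures=("left_arm_raised", "both_arms_raised"))
        frames = posture_stream(subject, camera, plan.postures)
        report = pw.run_rehab_session(frames, plan, upper_bundle, calibration=calibration)
        assert [e["achieved"] for e in report.entries] == [True, True]
        assert [e["attempts"] for e in report.entries] == [1, 1]

    def test_unshown_posture_exhausts_attempts(self, subject, camera, calibration, upper_bundle):
        plan = pw.RehabPlan(postures=("both_arms_raised",), max_train=3)
        frames = posture_stream(subject, camera, ["both_arms_down"] * 4)
        report = pw.run_rehab_session(frames, plan, upper_bundle, calibration=calibration)
        entry = report.entries[0]
        assert entry["achieved"] is False and entry["attempts"] == 3

    def test_exhausted_stream_marks_not_attempted(self, subject, camera, calibration, upper_bundle):
        plan = pw.RehabPlan(postures=("both_arms_down", "arms_outstretched", "left_arm_raised"))
        frames = posture_stream(subject, camera, ["both_arms_down"])  # 2 s only
        report = pw.run_rehab_session(frames, plan, upper_bundle, calibration=calibration)
        assert report.entries[0]["achieved"] is True
        assert {e["status"] for e in report.entries[1:]} == {"not-attempted"}

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            pw.RehabPlan(postures=())

    def test_report_serializes_every_planned_posture_in_order(
        self, subject, camera, calibration, upper_bundle
    ):
        import json

        plan = pw.RehabPlan(postures=("both_arms_down", "arms_outstretched"))
        frames = posture_stream(subject, camera, plan.postures)
        report = pw.run_rehab_session(frames, plan, upper_bundle, calibration=calibration)
        doc = json.loads(report.to_json())
        assert [e["posture"] for e in doc["postures"]] == list(plan.postures)
        assert doc["schema"].startswith("posewatch.session_report")

    def test_prompt_hook_called_on_retries(self, subject, camera, calibration, upper_bundle):
        plan = pw.RehabPlan(postures=("both_arms_raised",), max_train=2)
        frames = posture_stream(subject, camera, ["both_arms_down"] * 3)
        prompts = []
        pw.run_rehab_session(
            frames, plan, upper_bundle, calibration=calibration,
            prompt_hook=lambda p, n: prompts.append((p, n)),
        )
        assert prompts == [("both_arms_raised", 1)]
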