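"""Real-time orchestration: frame loop, fall alarm state machine, rehab driver.

Fall alarm escalation
---------------------
A detected fall starts a timer and walks the monitor through four stages:

``Normal``
    The subject is up and about; nothing pending.
``Abnormal``
    A fall was observed; the timer runs.  Standing back up before
    ``safety_time`` elapses discards the episode.
``Urgent``
    The subject has been down longer than ``safety_time``; an alarm is
    imminent.  Standing up still discards it.
``Emergency``
    Down longer than ``safety_time + urgent_grace``: the alarm fires and
    the stage latches — only a manual reset by an authorized person returns
    the monitor to ``Normal``.

Observations the machine consumes per frame: ``fall``, ``no_fall``,
``stand_up`` and ``no-observation`` (head not visible — the timer keeps
running, so a subject who falls out of view still escalates).

The rehabilitation driver walks a patient through an ordered plan of target
postures, granting a bounded number of timed attempts per posture and
reporting per-posture outcomes for the remote therapist.
"""

from __future__ import annotations

import itertools
import json
import logging
import warnings
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional

from .detectors import NO_OBSERVATION, ClassifierBundle
from .skeleton import (
    CalibrationError,
    Joint,
    JointMissingError,
    SkeletonFrame,
    SubjectCalibration,
)

__all__ = [
    "AlarmStage",
    "MonitorConfig",
    "MonitorState",
    "AlarmEvent",
    "RehabPlan",
    "SessionReport",
    "OBS_FALL",
    "OBS_NO_FALL",
    "OBS_STAND_UP",
    "OBS_NONE",
    "step_fall_monitor",
    "manual_reset",
    "run_monitor",
    "run_rehab_session",
]

log = logging.getLogger("posewatch.monitor")

OBS_FALL = "fall"
OBS_NO_FALL = "no_fall"
OBS_STAND_UP = "stand_up"
OBS_NONE = NO_OBSERVATION
_OBSERVATIONS = (OBS_FALL, OBS_NO_FALL, OBS_STAND_UP, OBS_NONE)


class AlarmStage(str, Enum):
    NORMAL = "Normal"
    ABNORMAL = "Abnormal"
    URGENT = "Urgent"
    EMERGENCY = "Emergency"


@dataclass(frozen=True)
class MonitorConfig:
    safety_time: float = 10.0
    urgent_grace: float = 5.0
    frame_rate: float = 30.0
    #: stand-up debounce: head must be back above this fraction of the
    #: standing head height, with the lower-body net reporting standing,
    #: for this long before a stand-up observation is emitted.
    standup_head_fraction: float = 0.8
    standup_hold: float = 0.5

    def __post_init__(self) -> None:
        for name in ("safety_time", "urgent_grace", "frame_rate", "standup_hold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AlarmEvent:
    kind: str  # stage_change | alarm_started | alarm_discarded | reset
    timestamp: float
    from_stage: AlarmStage
    to_stage: AlarmStage

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema": "posewatch.alarm_event.v1",
                "kind": self.kind,
                "timestamp": round(self.timestamp, 6),
                "from_stage": self.from_stage.value,
                "to_stage": self.to_stage.value,
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class MonitorState:
    stage: AlarmStage = AlarmStage.NORMAL
    fall_start: Optional[float] = None
    alarm_active: bool = False
    last_t: float = float("-inf")


def step_fall_monitor(
    state: MonitorState, observation: str, t: float, config: MonitorConfig
):
    """Advance the alarm state machine by one observation.

    Returns ``(new_state, events)``.  Escalation is time-driven — Abnormal
    becomes Urgent once the subject has been down longer than
    ``safety_time`` and Urgent becomes Emergency (firing the alarm) after
    ``safety_time + urgent_grace`` — and is applied before the observation,
    so a late stand-up cannot outrun an alarm that is already due.  A fall
    observation starts the timer only from Normal; continuous falls never
    restart an episode's timer.
    """
    if observation not in _OBSERVATIONS:
        raise ValueError(f"unknown observation: {observation!r}")
    if t < state.last_t:
        raise ValueError(f"time running backwards: {t} < {state.last_t}")

    events = []
    stage, fall_start = state.stage, state.fall_start

    def change(to_stage: AlarmStage, kind: str = "stage_change") -> None:
        nonlocal stage
        events.append(AlarmEvent(kind, t, stage, to_stage))
        stage = to_stage

    # time-driven escalation of a running episode
    if stage in (AlarmStage.ABNORMAL, AlarmStage.URGENT) and fall_start is not None:
        elapsed = t - fall_start
        if stage is AlarmStage.ABNORMAL and elapsed > config.safety_time:
            change(AlarmStage.URGENT)
        if stage is AlarmStage.URGENT and elapsed > config.safety_time + config.urgent_grace:
            change(AlarmStage.EMERGENCY)
            events.append(AlarmEvent("alarm_started", t, AlarmStage.URGENT, AlarmStage.EMERGENCY))

    # observation-driven transitions; Emergency ignores everything
    if stage is AlarmStage.NORMAL and observation == OBS_FALL:
        change(AlarmStage.ABNORMAL)
        fall_start = t
    elif stage in (AlarmStage.ABNORMAL, AlarmStage.URGENT) and observation == OBS_STAND_UP:
        events.append(AlarmEvent("alarm_discarded", t, stage, AlarmStage.NORMAL))
        change(AlarmStage.NORMAL)
        fall_start = None

    if stage is AlarmStage.NORMAL:
        fall_start = None
    new_state = MonitorState(
        stage=stage,
        fall_start=fall_start,
        alarm_active=stage is AlarmStage.EMERGENCY,
        last_t=t,
    )
    return new_state, events


def manual_reset(state: MonitorState, t: Optional[float] = None):
    """Authorized reset: Emergency -> Normal; elsewhere a warned no-op."""
    t = t if t is not None else max(state.last_t, 0.0)
    if state.stage is not AlarmStage.EMERGENCY:
        warnings.warn("manual reset ignored: monitor is not in Emergency", stacklevel=2)
        return state, [AlarmEvent("reset", t, state.stage, state.stage)]
    events = [AlarmEvent("reset", t, AlarmStage.EMERGENCY, AlarmStage.NORMAL)]
    return MonitorState(stage=AlarmStage.NORMAL, last_t=t), events


def _default_alarm_hook(event: AlarmEvent) -> None:
    log.warning("ALARM %s", event.to_json())


def run_monitor(
    frames: Iterable[SkeletonFrame],
    fall_bundle: ClassifierBundle,
    lower_bundle: Optional[ClassifierBundle],
    config: Optional[MonitorConfig] = None,
    calibration: Optional[SubjectCalibration] = None,
    alarm_hook: Optional[Callable[[AlarmEvent], None]] = None,
) -> list:
    """Run the per-frame loop over a stream and return the alarm events.

    Per frame the fall bundle classifies the sliding window of consecutive
    head positions (broken by head dropout); the stand-up observation is
    derived from the lower-body bundle reporting ``standing`` while the head
    has recovered to the configured fraction of its standing height for the
    debounce interval.  ``calibration`` defaults to an estimate from the
    first calibratable frame.  ``alarm_hook`` is invoked on every
    ``alarm_started`` event (default: a structured log line).
    """
    config = config or MonitorConfig()
    hook = alarm_hook or _default_alarm_hook
    frames = iter(frames)
    buffered = []
    if calibration is None:
        for frame in frames:
            buffered.append(frame)
            try:
                calibration = SubjectCalibration.from_frame(frame)
                break
            except (CalibrationError, ValueError):
                continue
        if calibration is None:
            return []  # nothing calibratable: empty or headless stream

    state = MonitorState()
    events: list[AlarmEvent] = []
    head_run: deque = deque(maxlen=fall_bundle.window)
    stand_since: Optional[float] = None
    head_threshold = config.standup_head_fraction * calibration.standing_head_y

    def lower_says_standing(frame: SkeletonFrame) -> bool:
        if lower_bundle is None:
            return False
        try:
            return lower_bundle.classify(frame, calibration) == "standing"
        except JointMissingError:
            return False

    for frame in itertools.chain(buffered, frames):
        t = frame.timestamp
        if frame.detected(Joint.HEAD):
            head_run.append(frame)
            head_y = float(frame.position(Joint.HEAD)[1])
            if head_y >= head_threshold and lower_says_standing(frame):
                stand_since = t if stand_since is None else stand_since
            else:
                stand_since = None
        else:
            head_run.clear()
            stand_since = None

        if stand_since is not None and t - stand_since >= config.standup_hold:
            observation = OBS_STAND_UP
        elif not frame.detected(Joint.HEAD):
            observation = OBS_NONE
        elif len(head_run) == fall_bundle.window:
            label = fall_bundle.classify(list(head_run), calibration)
            observation = OBS_FALL if label == "fall" else OBS_NO_FALL
        else:
            observation = OBS_NO_FALL

        state, step_events = step_fall_monitor(state, observation, t, config)
        for event in step_events:
            events.append(event)
            log.info("%s", event.to_json())
            if event.kind == "alarm_started":
                hook(event)
    return events


# ---------------------------------------------------------------------------
# Rehabilitation sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RehabPlan:
    """Ordered target postures with a per-posture attempt budget."""

    postures: tuple
    max_train: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "postures", tuple(self.postures))
        if not self.postures:
            raise ValueError("a rehabilitation plan needs at least one posture")
        if self.max_train < 1:
            raise ValueError("max_train must be >= 1")


@dataclass
class SessionReport:
    """Per-posture outcomes of one rehabilitation session (exportable JSON)."""

    entries: list = field(default_factory=list)
    schema: str = "posewatch.session_report.v1"

    def achieved(self) -> int:
        return sum(1 for e in self.entries if e["achieved"])

    def to_json(self) -> str:
        return json.dumps({"schema": self.schema, "postures": self.entries}, indent=2, sort_keys=True)


def run_rehab_session(
    frames: Iterable[SkeletonFrame],
    plan: RehabPlan,
    upper_bundle: ClassifierBundle,
    calibration: Optional[SubjectCalibration] = None,
    attempt_seconds: float = 2.0,
    success_fraction: float = 0.7,
    prompt_hook: Optional[Callable[[str, int], None]] = None,
) -> SessionReport:
    """Walk the stream through the plan, one timed attempt at a time.

    An attempt is an ``attempt_seconds`` evaluation window; it succeeds when
    at least ``success_fraction`` of its frames classify as the target
    posture.  Each posture gets up to ``plan.max_train`` attempts before the
    session moves on; when the stream runs out, remaining postures are
    marked not-attempted.  ``prompt_hook(posture, attempt)`` stands in for
    asking the user to try again.
    """
    frames = list(frames)
    if calibration is None:
        for frame in frames:
            try:
                calibration = SubjectCalibration.from_frame(frame)
                break
            except (CalibrationError, ValueError):
                continue
        if calibration is None and frames:
            raise CalibrationError("no calibratable frame in the session stream")

    report = SessionReport()
    pos = 0  # cursor into frames

    def next_window(start_index: int):
        if start_index >= len(frames):
            return None, start_index
        t0 = frames[start_index].timestamp
        window = []
        i = start_index
        while i < len(frames) and frames[i].timestamp < t0 + attempt_seconds:
            window.append(frames[i])
            i += 1
        if i >= len(frames) and (not window or window[-1].timestamp - t0 < 0.5 * attempt_seconds):
            return None, i  # too little tail to count as an attempt
        return window, i

    for posture in plan.postures:
        attempts = 0
        achieved = False
        started_at = None
        ended_at = None
        while attempts < plan.max_train and not achieved:
            window, pos = next_window(pos)
            if window is None:
                break
            attempts += 1
            started_at = window[0].timestamp if started_at is None else started_at
            ended_at = window[-1].timestamp
            hits = 0
            for frame in window:
                try:
                    if upper_bundle.classify(frame, calibration) == posture:
                        hits += 1
                except JointMissingError:
                    pass
            achieved = hits >= success_fraction * len(window)
            if not achieved and attempts < plan.max_train and prompt_hook is not None:
                prompt_hook(posture, attempts)
        report.entries.append(
            {
                "posture": posture,
                "attempts": attempts,
                "achieved": bool(achieved),
                "status": "completed" if attempts else "not-attempted",
                "started_at": started_at,
                "ended_at": ended_at,
            }
        )
    return report
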