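"""Parametric skeleton/camera simulator replacing the depth sensor.

The classifiers consume only named 3D joint coordinates, so a simulator that
emits labeled :class:`~posewatch.skeleton.SkeletonFrame` streams can stand in
for the camera and the recorded subjects.  It models

* a subject as a stick figure parameterized by stature and segment ratios
  (:class:`SubjectModel`),
* held postures as joint-angle templates (:data:`TEMPLATES`) — five
  upper-body arm configurations plus standing/sitting,
* motion as scripted timed events — posture holds, falls, and the fall-like
  confounders *quick sit* and *bend down* (:class:`MotionScript`),
* the camera as a pinhole with a finite field of view, additive Gaussian
  coordinate noise that grows beyond the sensor's useful depth range, a
  vertical viewing angle (camera raised and pitched at the subject) and a
  horizontal subject rotation (:class:`CameraModel`).

Joints outside the view frustum are reported undetected, which is the
mechanism behind the short-range failure regime: closer than about one meter
the head leaves the vertical field of view and fall windows can no longer be
assembled.

What the simulator does *not* model: occlusion by furniture or the subject's
own body, skeleton-tracker identity swaps, and the strongly non-Gaussian
error bursts of real trackers.  Results on this data are mechanism checks,
not field accuracy claims (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .skeleton import (
    ANCHOR_HIP_MID,
    ANCHOR_SHOULDER_MID,
    ANCHOR_STANDING_HEAD,
    Joint,
    SkeletonFrame,
    SubjectCalibration,
    extract_features,
)
from .neural import TrainingSet

__all__ = [
    "SubjectModel",
    "PostureTemplate",
    "CameraModel",
    "MotionScript",
    "ScriptEvent",
    "TEMPLATES",
    "UPPER_TEMPLATE_NAMES",
    "LOWER_TEMPLATE_NAMES",
    "subject_pool",
    "pose_joints",
    "enrollment_calibration",
    "render_posture",
    "render_script",
    "generate_posture_dataset",
    "generate_distractor_features",
    "generate_fall_windows",
    "stratified_counts",
]


@dataclass(frozen=True)
class SubjectModel:
    """Stick-figure subject: stature in meters plus segment fractions.

    The vertical chain ``leg + torso + head`` must render the standing head
    at the stature within 2%; widths and arm segments are fractions of the
    stature as well.
    """

    height: float = 1.70
    leg: float = 0.53  # floor -> hip
    torso: float = 0.29  # hip -> shoulder line
    head: float = 0.18  # shoulder line -> head joint
    shoulder_width: float = 0.24
    hip_width: float = 0.18
    upper_arm: float = 0.17
    forearm: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.height < 2.5):
            raise ValueError("implausible subject height")
        total = self.leg + self.torso + self.head
        if abs(total - 1.0) > 0.02:
            raise ValueError("leg + torso + head must sum to ~1.0 of stature")

    def scaled(self, new_height: float) -> "SubjectModel":
        return replace(self, height=new_height)


def subject_pool(n: int = 6, height_range=(1.50, 1.95), seed: int = 0) -> list:
    """``n`` subjects with statures evenly spaced over ``height_range``."""
    heights = np.linspace(height_range[0], height_range[1], n)
    return [SubjectModel(height=float(h), seed=seed + i) for i, h in enumerate(heights)]


@dataclass(frozen=True)
class PostureTemplate:
    """A held pose: per-arm elevation (degrees from straight down, in the
    coronal plane) plus a stance interpolation (0 = standing, 1 = seated)."""

    name: str
    left_arm_deg: float = 10.0
    right_arm_deg: float = 10.0
    sit_fraction: float = 0.0


UPPER_TEMPLATE_NAMES = (
    "both_arms_raised",
    "right_arm_raised",
    "left_arm_raised",
    "arms_outstretched",
    "both_arms_down",
)
LOWER_TEMPLATE_NAMES = ("standing", "sitting")

TEMPLATES = {
    "both_arms_raised": PostureTemplate("both_arms_raised", 170.0, 170.0),
    "right_arm_raised": PostureTemplate("right_arm_raised", 10.0, 170.0),
    "left_arm_raised": PostureTemplate("left_arm_raised", 170.0, 10.0),
    "arms_outstretched": PostureTemplate("arms_outstretched", 90.0, 90.0),
    "both_arms_down": PostureTemplate("both_arms_down", 10.0, 10.0),
    "standing": PostureTemplate("standing", 10.0, 10.0, sit_fraction=0.0),
    "sitting": PostureTemplate("sitting", 10.0, 10.0, sit_fraction=1.0),
}

# Stance geometry (fractions of stature): how far the pelvis drops when
# seated and how far knees/feet slide toward the camera.  Seated, the
# head-to-knee distance shrinks to ~0.47 of stature, well below the 2:3
# standing ratio, so the ratio baseline stays consistent with the templates.
# The tracked foot joint is the ankle center, a few cm above the floor.
_SIT_PELVIS_DROP = 0.26
_SIT_KNEE_FORWARD = 0.20
_SIT_FOOT_FORWARD = 0.14
_SIT_KNEE_LIFT = -0.01
_ANKLE_HEIGHT = 0.04

_JOINT_ORDER = tuple(Joint)
_JIDX = {j: i for i, j in enumerate(_JOINT_ORDER)}


def pose_joints(subject: SubjectModel, template: PostureTemplate) -> np.ndarray:
    """Joint positions (14 x 3, meters) in the subject-local frame.

    Local frame: x lateral (subject's right arm toward +x), y up from the
    floor, z toward the camera-away direction; the subject faces -z.
    """
    h = subject.height
    u = float(np.clip(template.sit_fraction, 0.0, 1.0))
    hip_y = (subject.leg - u * _SIT_PELVIS_DROP) * h
    drop = u * _SIT_PELVIS_DROP * h
    shoulder_y = (subject.leg + subject.torso) * h - drop
    head_y = h - drop
    knee_y = (0.52 * subject.leg + u * _SIT_KNEE_LIFT) * h
    knee_z = -u * _SIT_KNEE_FORWARD * h
    foot_z = -u * _SIT_FOOT_FORWARD * h
    sw = 0.5 * subject.shoulder_width * h
    hw = 0.5 * subject.hip_width * h

    P = np.zeros((len(_JOINT_ORDER), 3))

    def put(j: Joint, x, y, z) -> None:
        P[_JIDX[j]] = (x, y, z)

    put(Joint.HEAD, 0.0, head_y, 0.0)
    put(Joint.CENTER_SHOULDER, 0.0, shoulder_y, 0.0)
    put(Joint.LEFT_SHOULDER, -sw, shoulder_y, 0.0)
    put(Joint.RIGHT_SHOULDER, sw, shoulder_y, 0.0)
    for side, sign, adeg in (
        (("LEFT_ELBOW", "LEFT_HAND"), -1.0, template.left_arm_deg),
        (("RIGHT_ELBOW", "RIGHT_HAND"), 1.0, template.right_arm_deg),
    ):
        a = math.radians(adeg)
        direction = np.array([sign * math.sin(a), -math.cos(a), 0.0])
        shoulder = np.array([sign * sw, shoulder_y, 0.0])
        elbow = shoulder + subject.upper_arm * h * direction
        hand = elbow + subject.forearm * h * direction
        put(Joint[side[0]], *elbow)
        put(Joint[side[1]], *hand)
    put(Joint.LEFT_HIP, -hw, hip_y, 0.0)
    put(Joint.RIGHT_HIP, hw, hip_y, 0.0)
    put(Joint.LEFT_KNEE, -hw, knee_y, knee_z)
    put(Joint.RIGHT_KNEE, hw, knee_y, knee_z)
    put(Joint.LEFT_FOOT, -hw, _ANKLE_HEIGHT * h, foot_z)
    put(Joint.RIGHT_FOOT, hw, _ANKLE_HEIGHT * h, foot_z)
    return P


@dataclass(frozen=True)
class CameraModel:
    """Pinhole depth sensor aimed at the subject's mid-height point.

    ``vertical_angle`` raises the camera on an arc about that aim point and
    pitches it back down (positive = above the subject; 0 = parallel to the
    floor).  ``horizontal_rotation`` turns the subject about their own
    vertical axis.  Reported coordinates are camera-frame (x right, y up,
    z depth) with the y origin shifted to the floor, so at zero tilt a
    standing head sits near the subject's stature.

    Coordinate noise is zero-mean Gaussian with standard deviation
    ``noise_sigma0 * (1 + noise_z_scale * max(0, z - 4.5))``: flat inside
    the sensor's useful range, growing linearly beyond 4.5 m.
    """

    distance: float = 2.5
    vertical_angle: float = 0.0
    horizontal_rotation: float = 0.0
    v_fov: float = 50.0
    h_fov: float = 58.0
    noise_sigma0: float = 0.004
    noise_z_scale: float = 0.08
    frame_rate: float = 30.0
    #: minimum sensing depth (m) of the structured-light sensor class:
    #: joints closer than this are not tracked at all.
    near: float = 0.8
    #: Skeleton-fitting view dependence: the tracker assumes a roughly
    #: frontal, upright view, and beyond ``track_loss_onset`` degrees of
    #: vertical viewing angle it loses the whole skeleton on a growing
    #: fraction of frames (linear ramp over ``track_loss_ramp`` degrees,
    #: capped at 97%).  Horizontal rotation does not impair tracking.
    track_loss_onset: float = 35.0
    track_loss_ramp: float = 15.0
    seed: int = 0

    @property
    def track_loss_prob(self) -> float:
        excess = abs(self.vertical_angle) - self.track_loss_onset
        return float(np.clip(excess / self.track_loss_ramp, 0.0, 0.97))

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.v_fov <= 0 or self.h_fov <= 0:
            raise ValueError("field of view must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")


#: The camera is aimed slightly above the subject's mid-height so the whole
#: posture repertoire — floor-level feet up to overhead hands (~1.15 x
#: stature) — fits the vertical field of view at the 2.5 m working distance.
_AIM_FRACTION = 0.575


def _camera_geometry(subject: SubjectModel, camera: CameraModel):
    """Camera center and orthonormal basis (right, up, forward) in world."""
    alpha = math.radians(camera.vertical_angle)
    aim = np.array([0.0, _AIM_FRACTION * subject.height, 0.0])
    C = aim + camera.distance * np.array([0.0, math.sin(alpha), -math.cos(alpha)])
    f = np.array([0.0, -math.sin(alpha), math.cos(alpha)])
    r = np.array([1.0, 0.0, 0.0])
    up = np.array([0.0, math.cos(alpha), math.sin(alpha)])
    return C, r, up, f


def _project_points(
    world: np.ndarray,
    subject: SubjectModel,
    camera: CameraModel,
    jitter_sigma: float,
    rng: Optional[np.random.Generator],
):
    """World points (... x 3) -> reported camera coords + detected mask."""
    C, r, up, f = _camera_geometry(subject, camera)
    rel = world - C
    cam = np.stack([rel @ r, rel @ up, rel @ f], axis=-1)
    z = cam[..., 2]
    sigma = camera.noise_sigma0 * (1.0 + camera.noise_z_scale * np.maximum(0.0, z - 4.5))
    sigma = jitter_sigma + sigma
    if rng is not None:
        cam = cam + rng.normal(0.0, 1.0, size=cam.shape) * sigma[..., None]
        z = cam[..., 2]
    tan_h = math.tan(math.radians(camera.h_fov) / 2.0)
    tan_v = math.tan(math.radians(camera.v_fov) / 2.0)
    detected = (
        (z > camera.near)
        & (np.abs(cam[..., 0]) <= tan_h * z)
        & (np.abs(cam[..., 1]) <= tan_v * z)
    )
    loss = camera.track_loss_prob
    if loss > 0.0 and rng is not None and detected.ndim == 2:
        # whole-skeleton tracking loss on a per-frame basis at steep views
        lost = rng.random(detected.shape[0]) < loss
        detected = detected & ~lost[:, None]
    elif loss > 0.0 and rng is not None:
        if rng.random() < loss:
            detected = np.zeros_like(detected)
    cam = cam.copy()
    # Shift y so the floor point under the subject reads ~0: reported y is
    # the world point projected on the camera's (possibly tilted) up-axis,
    # which foreshortens vertical extents by cos(vertical_angle).
    cam[..., 1] += C @ up
    return cam, detected


def _rotate_y(points: np.ndarray, degrees: float) -> np.ndarray:
    a = math.radians(degrees)
    c, s = math.cos(a), math.sin(a)
    R = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return points @ R.T


def _frames_from_arrays(times, cam, detected) -> list:
    frames = []
    for t, pts, det in zip(times, cam, detected):
        positions = {
            joint: pts[i] for i, joint in enumerate(_JOINT_ORDER) if det[i]
        }
        frames.append(SkeletonFrame(timestamp=float(t), positions=positions))
    return frames


def enrollment_calibration(subject: SubjectModel, camera: CameraModel) -> SubjectCalibration:
    """Calibration as recorded at enrollment: the standing head height in the
    reported coordinate frame, computed geometrically (no noise, no frustum)."""
    world = _rotate_y(pose_joints(subject, TEMPLATES["standing"]), camera.horizontal_rotation)
    cam, _ = _project_points(world, subject, camera, jitter_sigma=0.0, rng=None)
    head_y = float(cam[_JIDX[Joint.HEAD], 1])
    return SubjectCalibration(height=subject.height, standing_head_y=head_y)


def render_posture(
    subject: SubjectModel,
    template,
    camera: CameraModel,
    jitter_sigma: float = 0.0,
    seed: Optional[int] = None,
    timestamp: float = 0.0,
) -> SkeletonFrame:
    """One frame of a held posture seen through the camera.

    ``template`` is a :class:`PostureTemplate` or a name in :data:`TEMPLATES`.
    ``jitter_sigma`` (meters) is per-coordinate pose jitter added on top of
    the camera's own noise model; ``seed=None`` renders noiselessly.
    """
    if isinstance(template, str):
        template = TEMPLATES[template]
    rng = None if seed is None and jitter_sigma == 0.0 else np.random.default_rng(seed)
    world = _rotate_y(pose_joints(subject, template), camera.horizontal_rotation)
    cam, det = _project_points(world, subject, camera, jitter_sigma, rng)
    return _frames_from_arrays([timestamp], cam[None], det[None])[0]


# ---------------------------------------------------------------------------
# Motion scripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScriptEvent:
    """One timed scene event.

    Kinds and parameters:

    ``hold``       posture (template name), duration
    ``fall``       duration_down (descent time), duration_on_ground
    ``quick_sit``  duration (descent, default 0.8 s), hold (seated time)
    ``bend_down``  drop_fraction of stature (<= 0.5), duration (down+up)
    ``stand_up``   duration (rise back to standing)
    """

    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "fall", "quick_sit", "bend_down", "stand_up"):
            raise ValueError(f"unknown script event: {self.kind!r}")
        for key, value in self.params.items():
            if key.startswith("duration") or key in ("hold",):
                if value <= 0:
                    raise ValueError(f"{self.kind}.{key} must be positive")


@dataclass(frozen=True)
class MotionScript:
    events: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        if not self.events:
            raise ValueError("a motion script needs at least one event")
        for ev in self.events:
            if not isinstance(ev, ScriptEvent):
                raise ValueError("script events must be ScriptEvent instances")


def hold(posture: str, duration: float) -> ScriptEvent:
    if posture not in TEMPLATES:
        raise ValueError(f"no template for posture {posture!r}")
    return ScriptEvent("hold", {"posture": posture, "duration": duration})


def fall(duration_down: float = 0.7, duration_on_ground: float = 12.0) -> ScriptEvent:
    if not (0.2 <= duration_down <= 2.0):
        raise ValueError("fall descent time out of plausible range")
    return ScriptEvent(
        "fall", {"duration_down": duration_down, "duration_on_ground": duration_on_ground}
    )


def quick_sit(duration: float = 0.8, hold: float = 4.0) -> ScriptEvent:
    return ScriptEvent("quick_sit", {"duration": duration, "hold": hold})


def bend_down(drop_fraction: float = 0.35, duration: float = 2.4) -> ScriptEvent:
    if not (0.0 < drop_fraction <= 0.5):
        raise ValueError("bend drop must be in (0, 0.5] of stature")
    return ScriptEvent("bend_down", {"drop_fraction": drop_fraction, "duration": duration})


def stand_up(duration: float = 0.8) -> ScriptEvent:
    return ScriptEvent("stand_up", {"duration": duration})


# Fallen pose: the body crumples in place; the head comes to rest at
# 0.2 * stature (kept above the floor so fall windows stay separable from a
# deep bend without being trivially so).
_FALL_HEAD_Y = 0.20
_FALL_BODY_Y = 0.10


def _fallen_joints(subject: SubjectModel) -> np.ndarray:
    P = pose_joints(subject, TEMPLATES["standing"]).copy()
    h = subject.height
    P[:, 1] = _FALL_BODY_Y * h
    P[_JIDX[Joint.HEAD], 1] = _FALL_HEAD_Y * h
    # limbs sprawl slightly along the floor
    P[_JIDX[Joint.LEFT_HAND], 0] -= 0.10 * h
    P[_JIDX[Joint.RIGHT_HAND], 0] += 0.10 * h
    P[_JIDX[Joint.HEAD], 2] -= 0.15 * h
    return P


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


class _ScriptState:
    """Tracks the current pose while laying out a script's timeline."""

    def __init__(self, subject: SubjectModel):
        self.subject = subject
        self.pose = pose_joints(subject, TEMPLATES["standing"])

    def blend_to(self, target: np.ndarray, n: int, ease=None) -> list:
        u = np.linspace(0.0, 1.0, n + 1)[1:]
        if ease is not None:
            u = ease(u)
        out = [(1.0 - ui) * self.pose + ui * target for ui in u]
        self.pose = target
        return out

    def hold_pose(self, n: int) -> list:
        return [self.pose.copy() for _ in range(n)]


def render_script(
    subject: SubjectModel,
    script: MotionScript,
    camera: CameraModel,
    seed: int = 0,
    jitter_sigma: float = 0.0,
) -> list:
    """Render a motion script to a strictly time-increasing frame stream.

    Returns a list of :class:`SkeletonFrame` at ``camera.frame_rate``;
    deterministic for a fixed seed.
    """
    if not isinstance(script, MotionScript):
        script = MotionScript(tuple(script))
    dt = 1.0 / camera.frame_rate
    state = _ScriptState(subject)
    poses: list[np.ndarray] = []

    def nframes(duration: float) -> int:
        return max(1, int(round(duration * camera.frame_rate)))

    for ev in script.events:
        p = ev.params
        if ev.kind == "hold":
            target = pose_joints(subject, TEMPLATES[p["posture"]])
            poses += state.blend_to(target, nframes(0.3))
            poses += state.hold_pose(nframes(p["duration"]))
        elif ev.kind == "fall":
            target = _fallen_joints(subject)
            # falls accelerate: quadratic ease-in
            poses += state.blend_to(target, nframes(p["duration_down"]), ease=lambda u: u**2)
            poses += state.hold_pose(nframes(p["duration_on_ground"]))
        elif ev.kind == "quick_sit":
            target = pose_joints(subject, TEMPLATES["sitting"])
            poses += state.blend_to(target, nframes(p["duration"]), ease=_smoothstep)
            poses += state.hold_pose(nframes(p["hold"]))
        elif ev.kind == "bend_down":
            bent = state.pose.copy()
            hip_y = 0.5 * (
                bent[_JIDX[Joint.LEFT_HIP], 1] + bent[_JIDX[Joint.RIGHT_HIP], 1]
            )
            head_y = bent[_JIDX[Joint.HEAD], 1]
            drop = p["drop_fraction"] * subject.height
            scale = max(0.05, 1.0 - drop / max(head_y - hip_y, 1e-9))
            upper = [
                Joint.HEAD,
                Joint.CENTER_SHOULDER,
                Joint.LEFT_SHOULDER,
                Joint.RIGHT_SHOULDER,
                Joint.LEFT_ELBOW,
                Joint.RIGHT_ELBOW,
                Joint.LEFT_HAND,
                Joint.RIGHT_HAND,
            ]
            for j in upper:
                i = _JIDX[j]
                bent[i, 1] = hip_y + (bent[i, 1] - hip_y) * scale
                bent[i, 2] -= 0.5 * drop  # torso pitches forward
            start = state.pose
            half = nframes(p["duration"] / 2.0)
            poses += state.blend_to(bent, half, ease=_smoothstep)
            poses += state.blend_to(start, half, ease=_smoothstep)
        elif ev.kind == "stand_up":
            target = pose_joints(subject, TEMPLATES["standing"])
            poses += state.blend_to(target, nframes(p["duration"]), ease=_smoothstep)

    world = _rotate_y(np.stack(poses), camera.horizontal_rotation)
    rng = np.random.default_rng(seed)
    cam, det = _project_points(world, subject, camera, jitter_sigma, rng)
    times = dt * np.arange(1, len(poses) + 1)
    return _frames_from_arrays(times, cam, det)


# ---------------------------------------------------------------------------
# Labeled dataset generation
# ---------------------------------------------------------------------------

_BODY_SETUP = {
    # body half -> (template names, default joint set getter, anchor)
    "upper": (UPPER_TEMPLATE_NAMES, ANCHOR_SHOULDER_MID),
    "lower": (LOWER_TEMPLATE_NAMES, ANCHOR_HIP_MID),
}


def _default_joint_set(body: str):
    from . import detectors  # local import to avoid a cycle

    return detectors.UPPER_JOINTS if body == "upper" else detectors.LOWER_JOINTS


def stratified_counts(total: int, n_classes: int) -> list:
    """Per-class counts for ``total`` samples, differing by at most one."""
    base, extra = divmod(total, n_classes)
    return [base + (1 if i < extra else 0) for i in range(n_classes)]


def generate_posture_dataset(
    body: str,
    n_total: int,
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    jitter_sigma: float = 0.02,
    seed: int = 0,
    joint_set=None,
    classes: Optional[Sequence[str]] = None,
) -> TrainingSet:
    """A stratified, shuffled posture training set for one body half.

    Every class receives ``n_total / n_classes`` samples (within one);
    each sample draws a subject from the pool, renders the class template
    with pose jitter through the camera, and runs the normalization
    pipeline.  Deterministic for a fixed seed.
    """
    if body not in _BODY_SETUP:
        raise ValueError("body must be 'upper' or 'lower'")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    template_names, anchor = _BODY_SETUP[body]
    if classes is not None:
        unknown = [c for c in classes if c not in TEMPLATES]
        if unknown:
            raise ValueError(f"no template for classes: {unknown}")
        template_names = tuple(classes)
    subjects = list(subjects) if subjects is not None else subject_pool()
    camera = camera if camera is not None else CameraModel()
    joint_set = tuple(joint_set) if joint_set is not None else _default_joint_set(body)

    rng = np.random.default_rng(seed)
    counts = stratified_counts(n_total, len(template_names))
    from .skeleton import JointMissingError

    rows, labels = [], []
    for name, count in zip(template_names, counts):
        for _ in range(count):
            # re-record on tracker dropout of a required joint (rare at the
            # default working distance; models "hold until tracked cleanly")
            for _attempt in range(50):
                subject = subjects[int(rng.integers(len(subjects)))]
                frame = render_posture(
                    subject,
                    TEMPLATES[name],
                    camera,
                    jitter_sigma=jitter_sigma,
                    seed=int(rng.integers(2**31)),
                )
                calib = enrollment_calibration(subject, camera)
                try:
                    fv = extract_features(frame, joint_set, calib, anchor=anchor)
                except JointMissingError:
                    continue
                break
            else:
                raise RuntimeError(
                    f"could not render a clean {name!r} frame at this camera setting"
                )
            rows.append(fv.values)
            labels.append(name)
    order = rng.permutation(len(rows))
    X = np.stack(rows)[order]
    y = np.asarray(labels)[order]
    return TrainingSet(X=X, y=y, labels=tuple(template_names))


def _template_distance(pose_a: np.ndarray, pose_b: np.ndarray, idx) -> float:
    """Largest per-joint displacement between two poses over ``idx`` joints."""
    return float(np.max(np.linalg.norm(pose_a[idx] - pose_b[idx], axis=1)))


def generate_distractor_features(
    body: str,
    n: int,
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    jitter_sigma: float = 0.02,
    seed: int = 0,
    min_sigma_distance: float = 3.0,
    joint_set=None,
) -> np.ndarray:
    """Feature rows for poses that match *no* trained class.

    Upper-body distractors draw independent random arm elevations; lower-body
    distractors draw an intermediate stance between standing and seated.  A
    candidate is kept only if some joint of the relevant set lies more than
    ``min_sigma_distance * jitter_sigma`` meters from its position in every
    class template (rendered for the same subject), i.e. the pose is outside
    every class's jitter cloud.
    """
    if body not in _BODY_SETUP:
        raise ValueError("body must be 'upper' or 'lower'")
    template_names, anchor = _BODY_SETUP[body]
    subjects = list(subjects) if subjects is not None else subject_pool()
    camera = camera if camera is not None else CameraModel()
    joint_set = tuple(joint_set) if joint_set is not None else _default_joint_set(body)
    idx = [_JIDX[Joint(j)] for j in joint_set]
    min_dist = min_sigma_distance * jitter_sigma

    rng = np.random.default_rng(seed)
    rows = []
    guard = 0
    while len(rows) < n:
        guard += 1
        if guard > 200 * n:
            raise RuntimeError("distractor rejection sampling failed to converge")
        subject = subjects[int(rng.integers(len(subjects)))]
        if body == "upper":
            cand = PostureTemplate(
                "distractor",
                left_arm_deg=float(rng.uniform(0.0, 180.0)),
                right_arm_deg=float(rng.uniform(0.0, 180.0)),
            )
        else:
            cand = PostureTemplate("distractor", sit_fraction=float(rng.uniform(0.0, 1.0)))
        pose = pose_joints(subject, cand)
        references = [pose_joints(subject, TEMPLATES[t]) for t in template_names]
        if any(_template_distance(pose, ref, idx) <= min_dist for ref in references):
            continue
        frame = render_posture(
            subject, cand, camera, jitter_sigma=jitter_sigma, seed=int(rng.integers(2**31))
        )
        calib = enrollment_calibration(subject, camera)
        try:
            fv = extract_features(frame, joint_set, calib, anchor=anchor)
        except Exception:
            continue  # joint dropped out of the frustum; resample
        rows.append(fv.values)
    return np.stack(rows)


def generate_fall_windows(
    n_fall: int,
    n_nonfall: int,
    subjects: Optional[Sequence[SubjectModel]] = None,
    camera: Optional[CameraModel] = None,
    window: int = 10,
    jitter_sigma: float = 0.02,
    seed: int = 0,
) -> TrainingSet:
    """Labeled head-trajectory windows for the fall/no-fall classifier.

    Fall windows come from scripted falls (descent times drawn from
    0.5–1.0 s plus on-ground frames); no-fall windows mix standing and
    seated holds with the quick-sit and bend-down confounders.  Each window
    is ``window`` consecutive head positions normalized against the
    subject's standing head height.
    """
    subjects = list(subjects) if subjects is not None else subject_pool()
    camera = camera if camera is not None else CameraModel()
    rng = np.random.default_rng(seed)

    def windows_from(frames, calib, start_t=None, end_t=None):
        out = []
        run = []
        for fr in frames:
            if not fr.detected(Joint.HEAD):
                run = []
                continue
            run.append(fr)
            if len(run) >= window:
                chunk = run[-window:]
                if start_t is not None and chunk[0].timestamp < start_t:
                    continue
                if end_t is not None and chunk[-1].timestamp > end_t:
                    continue
                fv = extract_features(
                    chunk, (Joint.HEAD,), calib, anchor=ANCHOR_STANDING_HEAD
                )
                out.append(fv.values)
        return out

    rows, labels = [], []
    # positives: scripted falls
    while sum(1 for l in labels if l == "fall") < n_fall:
        subject = subjects[int(rng.integers(len(subjects)))]
        calib = enrollment_calibration(subject, camera)
        t_down = float(rng.uniform(0.5, 1.0))
        script = MotionScript((hold("standing", 0.7), fall(t_down, 2.0)))
        frames = render_script(
            subject, script, camera, seed=int(rng.integers(2**31)), jitter_sigma=jitter_sigma
        )
        fall_start = 0.3 + 0.7  # blend-in + hold before the fall event
        got = windows_from(frames, calib, start_t=fall_start + 0.05)
        for values in got:
            if sum(1 for l in labels if l == "fall") >= n_fall:
                break
            rows.append(values)
            labels.append("fall")
    # negatives: holds and confounders in roughly equal shares
    makers = (
        lambda: MotionScript((hold("standing", 2.5),)),
        lambda: MotionScript((hold("sitting", 2.5),)),
        lambda: MotionScript((hold("standing", 0.7), quick_sit(0.8, 2.0))),
        lambda: MotionScript((hold("standing", 0.7), bend_down(0.35, 2.4))),
    )
    turn = 0
    while sum(1 for l in labels if l == "no_fall") < n_nonfall:
        subject = subjects[int(rng.integers(len(subjects)))]
        calib = enrollment_calibration(subject, camera)
        frames = render_script(
            subject,
            makers[turn % len(makers)](),
            camera,
            seed=int(rng.integers(2**31)),
            jitter_sigma=jitter_sigma,
        )
        turn += 1
        for values in windows_from(frames, calib):
            if sum(1 for l in labels if l == "no_fall") >= n_nonfall:
                break
            rows.append(values)
            labels.append("no_fall")
    order = rng.permutation(len(rows))
    X = np.stack(rows)[order]
    y = np.asarray(labels)[order]
    return TrainingSet(X=X, y=y, labels=("fall", "no_fall"))
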