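"""Skeleton frames, subject calibration and the normalized feature pipeline.

A depth camera's skeleton tracker emits, per video frame, 3D positions of a
fixed set of named body joints (meters, camera frame: x right, y up, z depth
away from the sensor).  Everything downstream — posture classifiers, the fall
detector, the alarm monitor — consumes those joint coordinates and nothing
else, so this module is the single place that defines

* the closed set of joints (:class:`Joint`),
* the per-frame container (:class:`SkeletonFrame`),
* subject calibration (standing height, standing head height),
* the normalization pipeline turning raw coordinates into network features
  in ``[0, 1]`` (:func:`extract_features`), and
* the plain-text frame-stream format used to record and replay sessions.

Normalization convention
------------------------
The feature pipeline is body-anchored and height-scaled so that features are
invariant to where the subject stands and to their stature:

1. translate every joint to an anchor (shoulder midpoint for upper-body
   joint sets, hip midpoint for lower-body sets, or the standing head
   reference for fall windows),
2. divide by the subject's calibrated height,
3. map ``[-1, 1]`` affinely onto ``[0, 1]`` and clip.

Sigmoid units expect inputs in ``[0, 1]``; the anchor choice makes the same
pose at 2 m and 3 m, or on a 1.5 m and a 1.95 m subject, produce identical
feature vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Joint",
    "Point3",
    "SkeletonFrame",
    "SubjectCalibration",
    "FeatureVector",
    "CalibrationError",
    "JointMissingError",
    "ANCHOR_SHOULDER_MID",
    "ANCHOR_HIP_MID",
    "ANCHOR_STANDING_HEAD",
    "estimate_height",
    "extract_features",
    "ratio_posture",
    "read_frames",
    "write_frames",
]


class Joint(str, Enum):
    """The closed set of tracked body joints."""

    HEAD = "head"
    CENTER_SHOULDER = "center_shoulder"
    LEFT_SHOULDER = "left_shoulder"
    RIGHT_SHOULDER = "right_shoulder"
    LEFT_ELBOW = "left_elbow"
    RIGHT_ELBOW = "right_elbow"
    LEFT_HAND = "left_hand"
    RIGHT_HAND = "right_hand"
    LEFT_HIP = "left_hip"
    RIGHT_HIP = "right_hip"
    LEFT_KNEE = "left_knee"
    RIGHT_KNEE = "right_knee"
    LEFT_FOOT = "left_foot"
    RIGHT_FOOT = "right_foot"

    def __str__(self) -> str:  # used by the stream writer
        return self.value


class CalibrationError(RuntimeError):
    """Subject height cannot be estimated from the available joints."""


class JointMissingError(LookupError):
    """A joint required by the consumer is not detected in a frame."""

    def __init__(self, joint: "Joint"):
        self.joint = joint
        super().__init__(f"required joint not detected: {joint.value}")


@dataclass(frozen=True)
class Point3:
    """A position in the camera frame (meters)."""

    x: float
    y: float
    z: float

    @property
    def array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def _as_xyz(value) -> np.ndarray:
    if isinstance(value, Point3):
        return value.array
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"joint position must be a 3-vector, got shape {arr.shape}")
    return arr


@dataclass
class SkeletonFrame:
    """One timestamped skeleton observation.

    ``positions`` maps each *detected* joint to its 3D position; a joint is
    detected iff it has an entry, so undetected joints are simply absent.
    """

    timestamp: float
    positions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = {Joint(j): _as_xyz(p) for j, p in self.positions.items()}

    def detected(self, joint: Joint) -> bool:
        return Joint(joint) in self.positions

    def position(self, joint: Joint) -> np.ndarray:
        """Position of ``joint`` or :class:`JointMissingError`."""
        joint = Joint(joint)
        try:
            return self.positions[joint]
        except KeyError:
            raise JointMissingError(joint) from None

    def translated(self, offset) -> "SkeletonFrame":
        """A copy with every joint shifted by ``offset`` (rigid translation)."""
        off = np.asarray(offset, dtype=float)
        return SkeletonFrame(
            timestamp=self.timestamp,
            positions={j: p + off for j, p in self.positions.items()},
        )


@dataclass(frozen=True)
class SubjectCalibration:
    """Per-subject reference values used by the normalization pipeline.

    ``height`` is the standing stature (meters); ``standing_head_y`` is the
    head joint's y-coordinate when the subject stands upright, expressed in
    the same frame as the streams being classified.  A pitched camera
    foreshortens vertical extents, so the observed standing head y may fall
    below the stature, but can never sit more than 10% above it.
    """

    height: float
    standing_head_y: float

    def __post_init__(self) -> None:
        if not (0.5 < self.height < 2.5):
            raise ValueError(f"implausible subject height: {self.height!r} m")
        if not (0.0 < self.standing_head_y <= 1.1 * self.height):
            raise ValueError(
                "standing_head_y inconsistent with height "
                f"({self.standing_head_y:.3f} vs {self.height:.3f})"
            )

    @classmethod
    def from_frame(cls, frame: SkeletonFrame) -> "SubjectCalibration":
        h = estimate_height(frame)
        return cls(height=h, standing_head_y=float(frame.position(Joint.HEAD)[1]))


@dataclass(frozen=True)
class FeatureVector:
    """Normalized network input: ``3 * len(joint_set) * n_frames`` values in [0,1]."""

    values: np.ndarray
    joint_set: tuple
    n_frames: int = 1

    def __len__(self) -> int:
        return len(self.values)


#: Anchor policies for :func:`extract_features`.
ANCHOR_SHOULDER_MID = "shoulder_mid"
ANCHOR_HIP_MID = "hip_mid"
ANCHOR_STANDING_HEAD = "standing_head"

_ANCHORS = (ANCHOR_SHOULDER_MID, ANCHOR_HIP_MID, ANCHOR_STANDING_HEAD)


def estimate_height(frame: SkeletonFrame) -> float:
    """Subject stature: head y minus the mean y of the detected feet.

    Falls back to a single foot when only one is tracked; raises
    :class:`CalibrationError` when the head or both feet are missing.
    """
    if not frame.detected(Joint.HEAD):
        raise CalibrationError("calibration impossible: head not detected")
    feet = [
        float(frame.positions[j][1])
        for j in (Joint.LEFT_FOOT, Joint.RIGHT_FOOT)
        if frame.detected(j)
    ]
    if not feet:
        raise CalibrationError("calibration impossible: no foot detected")
    height = float(frame.position(Joint.HEAD)[1]) - float(np.mean(feet))
    if height <= 0:
        raise CalibrationError(f"non-positive height estimate: {height:.3f} m")
    return height


def _frame_anchor(frame: SkeletonFrame, anchor: str) -> np.ndarray:
    if anchor == ANCHOR_SHOULDER_MID:
        return 0.5 * (
            frame.position(Joint.LEFT_SHOULDER) + frame.position(Joint.RIGHT_SHOULDER)
        )
    if anchor == ANCHOR_HIP_MID:
        return 0.5 * (frame.position(Joint.LEFT_HIP) + frame.position(Joint.RIGHT_HIP))
    raise ValueError(f"unknown anchor policy: {anchor!r}")


def extract_features(
    frames,
    joint_set: Sequence[Joint],
    calibration: SubjectCalibration,
    anchor: str = ANCHOR_SHOULDER_MID,
) -> FeatureVector:
    """Normalize one frame (posture) or a window of frames (fall) to [0, 1].

    Parameters
    ----------
    frames:
        A single :class:`SkeletonFrame` or a time-ordered sequence (oldest
        first; timestamps must be strictly increasing).
    joint_set:
        Ordered joints to extract; every joint must be detected in every
        frame (:class:`JointMissingError` otherwise).
    anchor:
        ``shoulder_mid`` / ``hip_mid`` anchor each frame at the named body
        midpoint.  ``standing_head`` anchors the whole window at
        ``(head.x, standing_head_y, head.z)`` of the *first* frame, so a
        descending head trajectory is expressed relative to where the head
        sits when the subject stands.
    """
    if isinstance(frames, SkeletonFrame):
        frames = [frames]
    else:
        frames = list(frames)
    if not frames:
        raise ValueError("extract_features requires at least one frame")
    ts = [f.timestamp for f in frames]
    if any(t1 >= t2 for t1, t2 in zip(ts, ts[1:])):
        raise ValueError("frame timestamps must be strictly increasing")
    joint_set = tuple(Joint(j) for j in joint_set)
    if anchor not in _ANCHORS:
        raise ValueError(f"unknown anchor policy: {anchor!r}")

    if anchor == ANCHOR_STANDING_HEAD:
        head0 = frames[0].position(Joint.HEAD)
        window_anchor = np.array([head0[0], calibration.standing_head_y, head0[2]])

    chunks = []
    for frame in frames:
        a = window_anchor if anchor == ANCHOR_STANDING_HEAD else _frame_anchor(frame, anchor)
        pts = np.stack([frame.position(j) for j in joint_set])
        rel = (pts - a) / calibration.height
        chunks.append(rel.reshape(-1))
    raw = np.concatenate(chunks)
    values = np.clip((raw + 1.0) / 2.0, 0.0, 1.0)
    return FeatureVector(values=values, joint_set=joint_set, n_frames=len(frames))


def ratio_posture(frame: SkeletonFrame, calibration: SubjectCalibration) -> str:
    """Threshold baseline: ``standing`` iff head-to-knee vertical distance is
    at least two thirds of the subject's height, else ``sitting``.

    The 2:3 ratio is the geometric signature of an upright stance; it roughly
    halves when the subject sits.  The boundary case (exactly 2/3) is assigned
    to ``standing``.
    """
    head_y = float(frame.position(Joint.HEAD)[1])
    knees = [
        float(frame.positions[j][1])
        for j in (Joint.LEFT_KNEE, Joint.RIGHT_KNEE)
        if frame.detected(j)
    ]
    if not knees:
        raise JointMissingError(Joint.LEFT_KNEE)
    distance = head_y - float(np.mean(knees))
    return "standing" if distance >= (2.0 / 3.0) * calibration.height else "sitting"


# ---------------------------------------------------------------------------
# Frame-stream files: one frame per line, '#' comments, missing joints omitted.
#   <timestamp> <joint>:<x>,<y>,<z> <joint>:<x>,<y>,<z> ...
# All numbers at 6 decimal places; reader/writer round-trip bit-exactly.
# ---------------------------------------------------------------------------


def write_frames(path, frames: Iterable[SkeletonFrame]) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# posewatch frame stream v1\n")
        for frame in frames:
            parts = [f"{frame.timestamp:.6f}"]
            for joint in Joint:  # canonical order keeps files diffable
                if frame.detected(joint):
                    x, y, z = frame.positions[joint]
                    parts.append(f"{joint.value}:{x:.6f},{y:.6f},{z:.6f}")
            fh.write(" ".join(parts) + "\n")


def read_frames(path) -> list:
    path = Path(path)
    frames: list[SkeletonFrame] = []
    last_t = -math.inf
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        try:
            t = float(tokens[0])
            positions = {}
            for token in tokens[1:]:
                name, coords = token.split(":")
                x, y, z = (float(v) for v in coords.split(","))
                positions[Joint(name)] = (x, y, z)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed frame line") from exc
        if t <= last_t:
            raise ValueError(f"{path}:{lineno}: timestamps must be strictly increasing")
        last_t = t
        frames.append(SkeletonFrame(timestamp=t, positions=positions))
    return frames
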