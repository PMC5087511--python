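"""Builders and runners for the three classifiers.

Three networks cover the monitored behaviors:

* **upper body** — five arm postures from 5 joints (15 inputs): the shoulder
  midpoint anchors the features and the shoulder pair is represented by the
  ``center_shoulder`` joint, so the set is center shoulder, elbows and hands.
  A 6-joint/18-input variant including both shoulders is available via
  ``joint_set=UPPER_JOINTS_18``.
* **lower body** — standing vs sitting from hips, knees and feet (18 inputs).
* **fall** — fall vs no-fall from a sliding window of 10 consecutive head
  positions (30 inputs at 30 fps, ~0.33 s): a single static head position
  cannot express an abrupt movement, the short window can.

Default hidden sizes are the empirically best 12 (upper) / 10 (lower); the
``size_hidden`` heuristic is available for other joint sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .neural import (
    BackpropMLP,
    NetworkConfig,
    TrainingSet,
    predict_label,
    size_hidden,
)
from .skeleton import (
    ANCHOR_HIP_MID,
    ANCHOR_SHOULDER_MID,
    ANCHOR_STANDING_HEAD,
    Joint,
    JointMissingError,
    SubjectCalibration,
    extract_features,
)

__all__ = [
    "UPPER_POSTURES",
    "LOWER_POSTURES",
    "FALL_LABELS",
    "UPPER_JOINTS",
    "UPPER_JOINTS_18",
    "LOWER_JOINTS",
    "FALL_WINDOW",
    "NO_OBSERVATION",
    "MissingClassError",
    "ClassifierBundle",
    "build_upper_classifier",
    "build_lower_classifier",
    "build_fall_classifier",
    "classify_frame",
]

UPPER_POSTURES = (
    "both_arms_raised",
    "right_arm_raised",
    "left_arm_raised",
    "arms_outstretched",
    "both_arms_down",
)
LOWER_POSTURES = ("standing", "sitting")
FALL_LABELS = ("fall", "no_fall")

UPPER_JOINTS = (
    Joint.CENTER_SHOULDER,
    Joint.LEFT_ELBOW,
    Joint.RIGHT_ELBOW,
    Joint.LEFT_HAND,
    Joint.RIGHT_HAND,
)
UPPER_JOINTS_18 = (
    Joint.LEFT_SHOULDER,
    Joint.RIGHT_SHOULDER,
    Joint.LEFT_ELBOW,
    Joint.RIGHT_ELBOW,
    Joint.LEFT_HAND,
    Joint.RIGHT_HAND,
)
LOWER_JOINTS = (
    Joint.LEFT_HIP,
    Joint.RIGHT_HIP,
    Joint.LEFT_KNEE,
    Joint.RIGHT_KNEE,
    Joint.LEFT_FOOT,
    Joint.RIGHT_FOOT,
)
FALL_WINDOW = 10

DEFAULT_HIDDEN_UPPER = 12
DEFAULT_HIDDEN_LOWER = 10

#: Returned by the fall bundle when the head is not visible.
NO_OBSERVATION = "no-observation"


class MissingClassError(ValueError):
    """The training set lacks one or more required classes."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"training set is missing classes: {', '.join(self.missing)}")


@dataclass
class ClassifierBundle:
    """A trained network plus everything needed to apply it to frames."""

    mlp: BackpropMLP
    joint_set: tuple
    labels: tuple
    anchor: str
    window: int = 1
    confidence_threshold: float = 0.5
    margin: float = 0.05

    def __post_init__(self) -> None:
        self.joint_set = tuple(Joint(j) for j in self.joint_set)
        self.labels = tuple(self.labels)
        expected = 3 * len(self.joint_set) * self.window
        if self.mlp.n_features_in_ != expected:
            raise ValueError(
                f"network has {self.mlp.n_features_in_} inputs but the joint "
                f"set/window imply {expected}"
            )
        if len(self.mlp.classes_) != len(self.labels):
            raise ValueError("label count does not match the network's outputs")

    @property
    def n_in(self) -> int:
        return self.mlp.n_features_in_

    def classify(self, frames, calibration: SubjectCalibration) -> str:
        """Extract features, run the network and decode a confident label.

        For the fall bundle a missing head yields ``"no-observation"``
        (there is nothing to classify); posture bundles propagate the
        joint-missing signal.
        """
        try:
            fv = extract_features(frames, self.joint_set, calibration, anchor=self.anchor)
        except JointMissingError:
            if self.anchor == ANCHOR_STANDING_HEAD:
                return NO_OBSERVATION
            raise
        if len(fv) != self.n_in:
            raise ValueError(
                f"feature length {len(fv)} does not match the network's {self.n_in} inputs"
            )
        outputs = self.mlp.decision_function(fv.values[None, :])[0]
        return predict_label(
            outputs,
            list(self.mlp.classes_),
            confidence_threshold=self.confidence_threshold,
            margin=self.margin,
        )


def _train_bundle(
    dataset: TrainingSet,
    required_labels: tuple,
    joint_set: tuple,
    anchor: str,
    window: int,
    n_hidden: int,
    config: Optional[NetworkConfig],
    confidence_threshold: float,
    margin: float,
) -> ClassifierBundle:
    if len(dataset) == 0:
        raise ValueError("empty training set")
    expected = 3 * len(joint_set) * window
    if dataset.X.shape[1] != expected:
        raise ValueError(
            f"dataset features have length {dataset.X.shape[1]}, expected {expected}"
        )
    present = set(map(str, dataset.y))
    missing = [c for c in required_labels if c not in present]
    if missing:
        raise MissingClassError(missing)
    if config is not None:
        mlp = BackpropMLP(
            n_hidden=config.n_hidden if config.n_hidden is not None else n_hidden,
            learning_rate=config.learning_rate,
            max_error=config.max_error,
            max_epochs=config.max_epochs,
            transfer=config.transfer,
            init_scale=config.init_scale,
            random_state=config.seed,
        )
    else:
        mlp = BackpropMLP(n_hidden=n_hidden)
    mlp.fit(dataset.X, np.asarray(list(map(str, dataset.y))))
    return ClassifierBundle(
        mlp=mlp,
        joint_set=joint_set,
        labels=tuple(mlp.classes_),
        anchor=anchor,
        window=window,
        confidence_threshold=confidence_threshold,
        margin=margin,
    )


def build_upper_classifier(
    dataset: TrainingSet,
    config: Optional[NetworkConfig] = None,
    joint_set=UPPER_JOINTS,
    confidence_threshold: float = 0.5,
    margin: float = 0.05,
) -> ClassifierBundle:
    """Train the five-posture upper-body classifier (15 inputs, hidden 12)."""
    return _train_bundle(
        dataset,
        UPPER_POSTURES,
        tuple(joint_set),
        ANCHOR_SHOULDER_MID,
        window=1,
        n_hidden=DEFAULT_HIDDEN_UPPER,
        config=config,
        confidence_threshold=confidence_threshold,
        margin=margin,
    )


def build_lower_classifier(
    dataset: TrainingSet,
    config: Optional[NetworkConfig] = None,
    joint_set=LOWER_JOINTS,
    confidence_threshold: float = 0.5,
    margin: float = 0.05,
) -> ClassifierBundle:
    """Train the standing/sitting lower-body classifier (18 inputs, hidden 10)."""
    return _train_bundle(
        dataset,
        LOWER_POSTURES,
        tuple(joint_set),
        ANCHOR_HIP_MID,
        window=1,
        n_hidden=DEFAULT_HIDDEN_LOWER,
        config=config,
        confidence_threshold=confidence_threshold,
        margin=margin,
    )


def build_fall_classifier(
    dataset: TrainingSet,
    config: Optional[NetworkConfig] = None,
    window: int = FALL_WINDOW,
    confidence_threshold: float = 0.5,
    margin: float = 0.05,
) -> ClassifierBundle:
    """Train the fall/no-fall classifier on head-trajectory windows.

    Inputs are ``3 * window`` (default 30); the hidden size defaults to the
    ``size_hidden`` heuristic for that topology.
    """
    return _train_bundle(
        dataset,
        FALL_LABELS,
        (Joint.HEAD,),
        ANCHOR_STANDING_HEAD,
        window=window,
        n_hidden=size_hidden(3 * window, len(FALL_LABELS)),
        config=config,
        confidence_threshold=confidence_threshold,
        margin=margin,
    )


def classify_frame(bundle: ClassifierBundle, frames, calibration: SubjectCalibration) -> str:
    """Functional alias for :meth:`ClassifierBundle.classify`."""
    return bundle.classify(frames, calibration)
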