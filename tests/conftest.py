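"""Shared fixtures: scene models and session-scoped trained classifiers.

The "fast" bundles trade training length for speed; they are used by tests
that exercise plumbing (monitoring, sessions, serialization), while accuracy
claims are tested at full study scale in test_acceptance.py.
"""

import logging

import pytest

import posewatch as pw
from posewatch.evaluation import train_fall_pipeline, train_posture_pair

logging.getLogger("posewatch.monitor").setLevel(logging.CRITICAL)


@pytest.fixture(scope="session")
def subject():
    return pw.SubjectModel(height=1.80)


@pytest.fixture(scope="session")
def camera():
    return pw.CameraModel()


@pytest.fixture(scope="session")
def calibration(subject, camera):
    return pw.enrollment_calibration(subject, camera)


@pytest.fixture(scope="session")
def posture_bundles():
    """Moderately trained upper/lower classifiers (shared, read-only)."""
    return train_posture_pair(11, n_train=(300, 300), max_epochs=6000)


@pytest.fixture(scope="session")
def upper_bundle(posture_bundles):
    return posture_bundles[0]


@pytest.fixture(scope="session")
def lower_bundle(posture_bundles):
    return posture_bundles[1]


@pytest.fixture(scope="session")
def fall_bundle(posture_bundles):
    bundle, _ = train_fall_pipeline(
        11, n_fall=250, n_nonfall=250, max_epochs=6000, lower_bundle=posture_bundles[1]
    )
    return bundle
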