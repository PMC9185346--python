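"""COCO-17 keypoint layout and the landmark sets used by the gait metrics.

The 17-landmark body model (nose, eyes, ears, shoulders, elbows, wrists,
hips, knees, ankles) is the output layout of common 2D pose estimators.
Index/name order here is the estimator output order and must never change.
"""

from __future__ import annotations

from enum import IntEnum

__all__ = [
    "Keypoint",
    "KEYPOINT_NAMES",
    "N_KEYPOINTS",
    "RELATIVE_ANGLE_DEFS",
    "ABSOLUTE_ANGLE_DEFS",
    "DISTANCE_PAIRS",
    "TORSO_KEYPOINTS",
]


class Keypoint(IntEnum):
    """COCO-17 landmark ids, in estimator output order."""

    NOSE = 0
    LEFT_EYE = 1
    RIGHT_EYE = 2
    LEFT_EAR = 3
    RIGHT_EAR = 4
    LEFT_SHOULDER = 5
    RIGHT_SHOULDER = 6
    LEFT_ELBOW = 7
    RIGHT_ELBOW = 8
    LEFT_WRIST = 9
    RIGHT_WRIST = 10
    LEFT_HIP = 11
    RIGHT_HIP = 12
    LEFT_KNEE = 13
    RIGHT_KNEE = 14
    LEFT_ANKLE = 15
    RIGHT_ANKLE = 16


KEYPOINT_NAMES: tuple[str, ...] = tuple(k.name.lower() for k in Keypoint)
N_KEYPOINTS = 17

K = Keypoint

#: Relative joint angles: angle between two limb vectors, each given as an
#: ordered pair (tail, head) so the vector is head - tail.  Elbow angles use
#: wrist->elbow vs elbow->shoulder; knee angles use hip->knee vs knee->ankle.
RELATIVE_ANGLE_DEFS: dict[str, tuple[tuple[Keypoint, Keypoint], tuple[Keypoint, Keypoint]]] = {
    "left_elbow": ((K.LEFT_WRIST, K.LEFT_ELBOW), (K.LEFT_ELBOW, K.LEFT_SHOULDER)),
    "right_elbow": ((K.RIGHT_WRIST, K.RIGHT_ELBOW), (K.RIGHT_ELBOW, K.RIGHT_SHOULDER)),
    "left_knee": ((K.LEFT_HIP, K.LEFT_KNEE), (K.LEFT_KNEE, K.LEFT_ANKLE)),
    "right_knee": ((K.RIGHT_HIP, K.RIGHT_KNEE), (K.RIGHT_KNEE, K.RIGHT_ANKLE)),
}

#: Absolute angles: undirected angle between a limb vector and the horizontal
#: image axis, for the eight bilateral wrist-elbow, elbow-shoulder, hip-knee
#: and knee-ankle vectors.
ABSOLUTE_ANGLE_DEFS: dict[str, tuple[Keypoint, Keypoint]] = {
    "left_wrist_elbow": (K.LEFT_WRIST, K.LEFT_ELBOW),
    "right_wrist_elbow": (K.RIGHT_WRIST, K.RIGHT_ELBOW),
    "left_elbow_shoulder": (K.LEFT_ELBOW, K.LEFT_SHOULDER),
    "right_elbow_shoulder": (K.RIGHT_ELBOW, K.RIGHT_SHOULDER),
    "left_hip_knee": (K.LEFT_HIP, K.LEFT_KNEE),
    "right_hip_knee": (K.RIGHT_HIP, K.RIGHT_KNEE),
    "left_knee_ankle": (K.LEFT_KNEE, K.LEFT_ANKLE),
    "right_knee_ankle": (K.RIGHT_KNEE, K.RIGHT_ANKLE),
}

#: Bilateral keypoint pairs whose inter-keypoint distance is tracked: the
#: shoulder and hip distances should be near-constant during frontal gait,
#: wrist and ankle distances carry the clinically relevant variability.
DISTANCE_PAIRS: dict[str, tuple[Keypoint, Keypoint]] = {
    "shoulders": (K.LEFT_SHOULDER, K.RIGHT_SHOULDER),
    "wrists": (K.LEFT_WRIST, K.RIGHT_WRIST),
    "hips": (K.LEFT_HIP, K.RIGHT_HIP),
    "ankles": (K.LEFT_ANKLE, K.RIGHT_ANKLE),
}

#: The rigid-torso anchors used by the scaling methods.
TORSO_KEYPOINTS: tuple[Keypoint, ...] = (
    K.LEFT_SHOULDER,
    K.RIGHT_SHOULDER,
    K.LEFT_HIP,
    K.RIGHT_HIP,
)
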