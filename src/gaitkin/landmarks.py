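"""BODY_25 landmark vocabulary.

OpenPose's BODY_25 model emits 25 keypoints per person, serialized as a
flat array of 75 floats (x, y, confidence per landmark) in the fixed index
order below.  Downstream kinematics requires a 16-landmark subset (trunk,
pelvis, and both lower limbs including heel and toe keypoints).
"""

from __future__ import annotations

from enum import IntEnum


class Landmark(IntEnum):
    """BODY_25 landmark identifiers, valued by their OpenPose array index."""

    Nose = 0
    Neck = 1
    RShoulder = 2
    RElbow = 3
    RWrist = 4
    LShoulder = 5
    LElbow = 6
    LWrist = 7
    MidHip = 8
    RHip = 9
    RKnee = 10
    RAnkle = 11
    LHip = 12
    LKnee = 13
    LAnkle = 14
    REye = 15
    LEye = 16
    REar = 17
    LEar = 18
    LBigToe = 19
    LSmallToe = 20
    LHeel = 21
    RBigToe = 22
    RSmallToe = 23
    RHeel = 24


N_LANDMARKS = 25

#: Landmarks required by the kinematics, event-detection and spatiotemporal
#: modules; a trajectory set missing any of these cannot be analysed.
REQUIRED_LANDMARKS = (
    Landmark.Neck,
    Landmark.MidHip,
    Landmark.RHip,
    Landmark.LHip,
    Landmark.RKnee,
    Landmark.LKnee,
    Landmark.RAnkle,
    Landmark.LAnkle,
    Landmark.RHeel,
    Landmark.LHeel,
    Landmark.RBigToe,
    Landmark.LBigToe,
    Landmark.RSmallToe,
    Landmark.LSmallToe,
    Landmark.RShoulder,
    Landmark.LShoulder,
)

LANDMARK_NAMES = tuple(lm.name for lm in sorted(Landmark, key=int))


def side_landmark(base: str, side: str) -> Landmark:
    """Return the landmark for ``base`` ('Hip', 'Knee', ...) on ``side``.

    >>> side_landmark("Knee", "right")
    <Landmark.RKnee: 10>
    """
    prefix = {"right": "R", "left": "L"}[side]
    return Landmark[prefix + base]
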