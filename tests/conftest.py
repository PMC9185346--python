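import numpy as np
import pytest

from gaitnorm import GaitSegment, Pose
from gaitnorm.keypoints import N_KEYPOINTS


def make_pose(frame_index=0, rng=None, overrides=None, confidence=0.9):
    """A random (or partially pinned) 17-keypoint pose.

    Coordinates are uniform in a generous image box, which keeps every
    scaling method's extents O(100) px — safely away from the degenerate
    guard.  ``overrides`` maps keypoint index -> (x, y).
    """
    rng = rng or np.random.default_rng(0)
    x = rng.uniform(300, 900, N_KEYPOINTS)
    y = rng.uniform(100, 600, N_KEYPOINTS)
    if overrides:
        for k, (xv, yv) in overrides.items():
            x[int(k)], y[int(k)] = xv, yv
    return Pose(frame_index=frame_index, x=x, y=y,
                confidence=np.full(N_KEYPOINTS, float(confidence)))


def make_segment(n_frames=5, rng=None, **meta):
    rng = rng or np.random.default_rng(0)
    poses = [make_pose(frame_index=i, rng=rng) for i in range(n_frames)]
    return GaitSegment.from_poses(poses, **meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_segment(rng):
    return make_segment(n_frames=8, rng=rng, participant_id="P01",
                        group="CON", direction="towards", segment_label="s1")
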