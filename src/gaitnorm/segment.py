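"""Core containers: a single-frame :class:`Pose` and an array-backed
:class:`GaitSegment` (an ordered pose sequence with study metadata).

Coordinates are pixels in the estimator's image convention: origin at the
top-left corner, y increasing downward, 0-based frame indices.  All the
downstream geometry is convention-agnostic except the sign of raw absolute
angles, and every reported metric is signless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .keypoints import N_KEYPOINTS

__all__ = ["Pose", "GaitSegment", "GROUPS", "DIRECTIONS"]

GROUPS = ("EOA", "DCD", "CON")
DIRECTIONS = ("towards", "away")


@dataclass(frozen=True)
class Pose:
    """One frame's 17 keypoint coordinates (pixels) and confidences."""

    frame_index: int
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "confidence"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_KEYPOINTS,):
                raise ValueError(f"{name} must have shape (17,), got {arr.shape}")
            object.__setattr__(self, name, arr)
        if self.frame_index < 0:
            raise ValueError("frame_index must be non-negative")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("keypoint coordinates must be finite")
        if ((self.confidence < 0) | (self.confidence > 1)).any():
            raise ValueError("confidences must lie in [0, 1]")


@dataclass
class GaitSegment:
    """An ordered sequence of >=2 poses with participant/group/direction metadata.

    Internally array-backed: ``x``, ``y`` and ``confidence`` are (n_frames, 17)
    float arrays and ``frame_indices`` is strictly increasing.
    """

    frame_indices: np.ndarray
    x: np.ndarray
    y: np.ndarray
    confidence: np.ndarray
    participant_id: str = ""
    group: str = "CON"
    direction: str = "towards"
    segment_label: str = ""

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        n = self.frame_indices.shape[0]
        if n < 2:
            raise ValueError("segment too short: need at least 2 frames")
        for name in ("x", "y", "confidence"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, N_KEYPOINTS):
                raise ValueError(f"{name} must have shape ({n}, 17), got {arr.shape}")
            setattr(self, name, arr)
        if (np.diff(self.frame_indices) <= 0).any():
            raise ValueError("frame indices must be strictly increasing")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")

    @classmethod
    def from_poses(
        cls,
        poses: Sequence[Pose],
        participant_id: str = "",
        group: str = "CON",
        direction: str = "towards",
        segment_label: str = "",
    ) -> "GaitSegment":
        poses = sorted(poses, key=lambda p: p.frame_index)
        return cls(
            frame_indices=np.array([p.frame_index for p in poses], dtype=int),
            x=np.stack([p.x for p in poses]) if poses else np.empty((0, N_KEYPOINTS)),
            y=np.stack([p.y for p in poses]) if poses else np.empty((0, N_KEYPOINTS)),
            confidence=np.stack([p.confidence for p in poses]) if poses else np.empty((0, N_KEYPOINTS)),
            participant_id=participant_id,
            group=group,
            direction=direction,
            segment_label=segment_label,
        )

    @property
    def n_frames(self) -> int:
        return int(self.frame_indices.shape[0])

    @property
    def poses(self) -> Iterator[Pose]:
        for i in range(self.n_frames):
            yield Pose(
                frame_index=int(self.frame_indices[i]),
                x=self.x[i].copy(),
                y=self.y[i].copy(),
                confidence=self.confidence[i].copy(),
            )

    def take(self, mask_or_index: np.ndarray) -> "GaitSegment":
        """Sub-segment keeping the selected frames, metadata carried through."""
        return replace(
            self,
            frame_indices=self.frame_indices[mask_or_index].copy(),
            x=self.x[mask_or_index].copy(),
            y=self.y[mask_or_index].copy(),
            confidence=self.confidence[mask_or_index].copy(),
        )

    def with_coordinates(self, x: np.ndarray, y: np.ndarray) -> "GaitSegment":
        """New segment with replaced coordinates; confidences and metadata kept."""
        return replace(self, x=np.asarray(x, float).copy(), y=np.asarray(y, float).copy(),
                       frame_indices=self.frame_indices.copy(),
                       confidence=self.confidence.copy())

    def metadata(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "group": self.group,
            "direction": self.direction,
            "segment_label": self.segment_label,
        }
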