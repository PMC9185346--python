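"""Frame exclusion and keypoint-confidence ("likelihood") summaries.

Frames in which body parts are occluded or lost carry low prediction
confidence; they are excluded before normalization because the scaling
anchors (shoulders, hips) must be reliably located.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .keypoints import Keypoint, TORSO_KEYPOINTS
from .segment import GaitSegment

__all__ = ["CleaningPolicy", "filter_frames", "likelihood_summary"]


@dataclass(frozen=True)
class CleaningPolicy:
    """Frame-exclusion rule.

    A frame is removed iff any *required* keypoint has confidence below
    ``min_keypoint_confidence``, or the fraction of all 17 keypoints at or
    above that threshold falls below ``min_fraction_valid``.

    Defaults require the four torso anchors (shoulders and hips, the
    landmarks every scaling method relies on) at confidence >= 0.3 and at
    least half of all keypoints valid.
    """

    min_keypoint_confidence: float = 0.3
    required_keypoints: frozenset[Keypoint] = frozenset(TORSO_KEYPOINTS)
    min_fraction_valid: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_keypoint_confidence <= 1.0:
            raise ValueError("min_keypoint_confidence must be in [0, 1]")
        if not 0.0 <= self.min_fraction_valid <= 1.0:
            raise ValueError("min_fraction_valid must be in [0, 1]")
        object.__setattr__(self, "required_keypoints",
                           frozenset(Keypoint(k) for k in self.required_keypoints))


def filter_frames(segment: GaitSegment,
                  policy: CleaningPolicy = CleaningPolicy()) -> tuple[GaitSegment, np.ndarray]:
    """Drop unusable frames; return the cleaned segment and removed frame indices.

    Raises if fewer than 2 frames survive ("segment exhausted by cleaning").
    """
    conf = segment.confidence
    valid = conf >= policy.min_keypoint_confidence  # (n, 17)
    keep = valid.mean(axis=1) >= policy.min_fraction_valid
    if policy.required_keypoints:
        req = np.array(sorted(int(k) for k in policy.required_keypoints))
        keep &= valid[:, req].all(axis=1)
    removed = segment.frame_indices[~keep].copy()
    if keep.sum() < 2:
        raise ValueError("segment exhausted by cleaning: fewer than 2 frames remain")
    return segment.take(keep), removed


def likelihood_summary(segments: list[GaitSegment],
                       unit: str = "segment") -> tuple[np.ndarray, float, float]:
    """Mean keypoint confidence per summary unit, plus grand mean and SD.

    ``unit`` is ``"segment"`` (one unit per segment: the mean over its
    frames x 17 keypoints) or ``"participant_direction"`` (segments pooled
    per participant and walking direction before averaging).  The grand SD
    uses the n-1 denominator and is 0 for a single unit.
    """
    if not segments:
        raise ValueError("need at least one segment")
    if unit == "segment":
        unit_means = np.array([s.confidence.mean() for s in segments])
    elif unit == "participant_direction":
        pooled: dict[tuple[str, str], list[np.ndarray]] = {}
        for s in segments:
            pooled.setdefault((s.participant_id, s.direction), []).append(
                s.confidence.ravel())
        unit_means = np.array(
            [np.concatenate(v).mean() for v in pooled.values()])
    else:
        raise ValueError(f"unknown summary unit {unit!r}")
    grand_mean = float(unit_means.mean())
    grand_sd = float(unit_means.std(ddof=1)) if unit_means.size > 1 else 0.0
    return unit_means, grand_mean, grand_sd
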