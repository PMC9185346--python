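"""Two-step skeleton normalization: position shifting plus size scaling.

Freehand single-camera gait video has two nonphysiological sources of
frame-to-frame variability: the skeleton size changes with distance from
the camera, and its position drifts with handheld-camera instability.
Normalization removes both so that distance-based gait features become
comparable across frames and segments.

Step 1 (position shifting) translates each frame so the mid-shoulder point
is the origin.  Step 2 (size scaling) rescales each frame by a per-frame
width/height (w_i, h_i) relative to their segment means (w0, h0); seven
variants differ in how (w_i, h_i) is defined.  A final recentering offset
(x0, y0) places the skeleton back in the image for visualization.  For a
keypoint (x, y) in frame i with mid-shoulder (mx_i, my_i):

    x' = (w0 / w_i) * (x - mx_i) + x0
    y' = (h0 / h_i) * (y - my_i) + y0

Four methods are anisotropic (w and h from bounding-box extents): BoN (all
17 keypoints), S (the two shoulders), LS_RH (left shoulder / right hip),
H (the two hips).  Three are isotropic (w = h from a Euclidean distance):
LS_RH_d (left shoulder to right hip), MS_MH_d (mid-shoulder to mid-hip),
ASH (average of both shoulder-to-opposite-hip diagonals).  Only the
isotropic methods preserve angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .keypoints import Keypoint as K
from .segment import GaitSegment, Pose

__all__ = [
    "NormalizationMethod",
    "ISOTROPIC_METHODS",
    "ReferenceScale",
    "RecenterOffset",
    "DegenerateFrameError",
    "EPSILON_PX",
    "position_shift",
    "frame_scale",
    "segment_reference",
    "normalize_segment",
]

logger = logging.getLogger(__name__)

#: Scale guard in pixels; anything smaller is below pixel quantization.
EPSILON_PX = 1e-6


class NormalizationMethod(str, Enum):
    """The seven size-scaling rules."""

    BON = "bon"          # bounding box of all 17 keypoints
    S = "s"              # shoulder bounding box
    H = "h"              # hip bounding box
    LS_RH = "ls-rh"      # left-shoulder / right-hip bounding box
    LS_RH_D = "ls-rh-d"  # left-shoulder to right-hip distance (isotropic)
    MS_MH_D = "ms-mh-d"  # mid-shoulder to mid-hip distance (isotropic)
    ASH = "ash"          # average shoulder-hip diagonal distance (isotropic)

    @property
    def isotropic(self) -> bool:
        return self in ISOTROPIC_METHODS


ISOTROPIC_METHODS = frozenset(
    {NormalizationMethod.LS_RH_D, NormalizationMethod.MS_MH_D, NormalizationMethod.ASH}
)


class DegenerateFrameError(ValueError):
    """A frame whose reference width or height collapses below the guard."""

    def __init__(self, method: "NormalizationMethod", frame_index: int,
                 w: float, h: float) -> None:
        self.method = method
        self.frame_index = frame_index
        super().__init__(
            f"degenerate frame {frame_index} for method {method.value}: "
            f"w={w:.3g}, h={h:.3g} (guard {EPSILON_PX:g} px)"
        )


@dataclass(frozen=True)
class RecenterOffset:
    """Constant recentering shift; (640, 200) suits 1280x720 footage."""

    x0: float = 640.0
    y0: float = 200.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x0) and np.isfinite(self.y0)):
            raise ValueError("offset must be finite")


@dataclass(frozen=True)
class ReferenceScale:
    """Per-frame scales and their segment means for one method."""

    per_frame_w: np.ndarray
    per_frame_h: np.ndarray
    w0: float
    h0: float
    retained: np.ndarray  # boolean mask over the segment's frames


def _mid_shoulder(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return (
        0.5 * (x[..., K.LEFT_SHOULDER] + x[..., K.RIGHT_SHOULDER]),
        0.5 * (y[..., K.LEFT_SHOULDER] + y[..., K.RIGHT_SHOULDER]),
    )


def position_shift(pose: Pose) -> Pose:
    """Translate a pose so its mid-shoulder point is exactly (0, 0)."""
    mx, my = _mid_shoulder(pose.x, pose.y)
    if not (np.isfinite(mx) and np.isfinite(my)):
        raise ValueError("non-finite shoulder coordinates")
    return Pose(frame_index=pose.frame_index, x=pose.x - mx, y=pose.y - my,
                confidence=pose.confidence)


def _frame_scales_arrays(x: np.ndarray, y: np.ndarray,
                         method: NormalizationMethod) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (w_i, h_i) for coordinate arrays of shape (..., 17)."""
    m = NormalizationMethod(method)
    if m is NormalizationMethod.BON:
        w = x.max(axis=-1) - x.min(axis=-1)
        h = y.max(axis=-1) - y.min(axis=-1)
    elif m is NormalizationMethod.S:
        w = np.abs(x[..., K.LEFT_SHOULDER] - x[..., K.RIGHT_SHOULDER])
        h = np.abs(y[..., K.LEFT_SHOULDER] - y[..., K.RIGHT_SHOULDER])
    elif m is NormalizationMethod.H:
        w = np.abs(x[..., K.LEFT_HIP] - x[..., K.RIGHT_HIP])
        h = np.abs(y[..., K.LEFT_HIP] - y[..., K.RIGHT_HIP])
    elif m is NormalizationMethod.LS_RH:
        w = np.abs(x[..., K.LEFT_SHOULDER] - x[..., K.RIGHT_HIP])
        h = np.abs(y[..., K.LEFT_SHOULDER] - y[..., K.RIGHT_HIP])
    elif m is NormalizationMethod.LS_RH_D:
        d = np.hypot(x[..., K.LEFT_SHOULDER] - x[..., K.RIGHT_HIP],
                     y[..., K.LEFT_SHOULDER] - y[..., K.RIGHT_HIP])
        w = h = d
    elif m is NormalizationMethod.MS_MH_D:
        mx, my = _mid_shoulder(x, y)
        hx = 0.5 * (x[..., K.LEFT_HIP] + x[..., K.RIGHT_HIP])
        hy = 0.5 * (y[..., K.LEFT_HIP] + y[..., K.RIGHT_HIP])
        d = np.hypot(mx - hx, my - hy)
        w = h = d
    elif m is NormalizationMethod.ASH:
        d1 = np.hypot(x[..., K.LEFT_SHOULDER] - x[..., K.RIGHT_HIP],
                      y[..., K.LEFT_SHOULDER] - y[..., K.RIGHT_HIP])
        d2 = np.hypot(x[..., K.RIGHT_SHOULDER] - x[..., K.LEFT_HIP],
                      y[..., K.RIGHT_SHOULDER] - y[..., K.LEFT_HIP])
        w = h = 0.5 * (d1 + d2)
    else:  # pragma: no cover
        raise ValueError(f"unknown method {method!r}")
    return np.asarray(w, float), np.asarray(h, float)


def frame_scale(pose: Pose, method: NormalizationMethod) -> tuple[float, float]:
    """The (w, h) reference scale of one frame under ``method``.

    Raises :class:`DegenerateFrameError` if either extent collapses below
    the epsilon guard (e.g. the hip bounding-box height of a level pelvis).
    """
    w, h = _frame_scales_arrays(pose.x, pose.y, method)
    w, h = float(w), float(h)
    if w < EPSILON_PX or h < EPSILON_PX:
        raise DegenerateFrameError(NormalizationMethod(method), pose.frame_index, w, h)
    return w, h


def segment_reference(segment: GaitSegment, method: NormalizationMethod,
                      on_degenerate: str = "error") -> ReferenceScale:
    """Per-frame scales and their means (w0, h0) over one segment.

    Scales are computed from the original (unshifted) coordinates — all
    seven methods are translation-invariant, so this is equivalent to using
    shifted ones, and stated for determinism.  Averages are taken over the
    retained frames of this segment only, never pooled across segments.

    ``on_degenerate``: ``"error"`` raises on the first degenerate frame;
    ``"skip"`` drops such frames from the reference (and, downstream, from
    the output) with a warning.
    """
    if on_degenerate not in ("error", "skip"):
        raise ValueError("on_degenerate must be 'error' or 'skip'")
    w, h = _frame_scales_arrays(segment.x, segment.y, method)
    ok = (w >= EPSILON_PX) & (h >= EPSILON_PX)
    if not ok.all():
        bad = int(np.flatnonzero(~ok)[0])
        if on_degenerate == "error":
            raise DegenerateFrameError(NormalizationMethod(method),
                                       int(segment.frame_indices[bad]),
                                       float(w[bad]), float(h[bad]))
        logger.warning("method %s: skipping %d degenerate frame(s)",
                       NormalizationMethod(method).value, int((~ok).sum()))
    if not ok.any():
        raise ValueError("all frames degenerate; no reference scale")
    return ReferenceScale(per_frame_w=w, per_frame_h=h,
                          w0=float(w[ok].mean()), h0=float(h[ok].mean()),
                          retained=ok)


def normalize_segment(segment: GaitSegment, method: NormalizationMethod,
                      offset: RecenterOffset = RecenterOffset(),
                      on_degenerate: str = "error") -> GaitSegment:
    """Apply position shifting, size scaling and recentering to a segment.

    After normalization the mid-shoulder point of every frame is exactly
    (x0, y0) and the method's own reference extent equals (w0, h0) in every
    frame.  Confidences, frame indices and metadata are carried through
    unchanged.  Outputs are not clipped to the image: clipping would corrupt
    distances.
    """
    ref = segment_reference(segment, method, on_degenerate=on_degenerate)
    out = segment if ref.retained.all() else segment.take(ref.retained)
    w = ref.per_frame_w[ref.retained]
    h = ref.per_frame_h[ref.retained]
    mx, my = _mid_shoulder(out.x, out.y)
    x = (ref.w0 / w)[:, None] * (out.x - mx[:, None]) + offset.x0
    y = (ref.h0 / h)[:, None] * (out.y - my[:, None]) + offset.y0
    return out.with_coordinates(x, y)
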