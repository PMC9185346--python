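"""Synthetic 17-keypoint walking skeletons with known ground truth.

The generator emulates what a pose estimator returns for a child walking
towards or away from a handheld camera in the coronal plane:

* a canonical body-frame walker with a rigid torso and sinusoidally
  swinging limbs (``make_walker``);
* camera effects — a monotone per-frame scale trajectory (distance to the
  camera under weak perspective), handheld translation jitter, additive
  keypoint noise, per-keypoint confidence scores and occasional dropout
  (``project_to_camera``).

Weak perspective (per-frame uniform scaling) is deliberate: it is exactly
the variability class the normalization removes, so test failures are
attributable to the implementation rather than to model mismatch.
Out-of-plane rotation is excluded.

Group profiles differ only in limb-swing variability: the EOA profile has
larger cycle-to-cycle swing-amplitude variability and larger within-cycle
angle jitter than DCD, which exceeds CON.  Every run is bit-reproducible
from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import Detection
from .keypoints import Keypoint as K
from .segment import GaitSegment, Pose

__all__ = [
    "SyntheticGaitConfig",
    "SyntheticGaitTruth",
    "PROFILE_PARAMS",
    "make_walker",
    "project_to_camera",
    "simulate_segment",
    "segment_to_detections",
]

#: (cycle-to-cycle swing-amplitude coefficient of variation,
#:  within-cycle angle jitter SD in degrees) per clinical profile.
PROFILE_PARAMS: dict[str, tuple[float, float]] = {
    "CON": (0.07, 0.5),
    "DCD": (0.15, 1.5),
    "EOA": (0.40, 4.0),
}

# substream labels (see _stream)
_CYCLES, _LIMB_JITTER, _CAM_JITTER, _KP_NOISE, _CONFIDENCE, _DROPOUT = range(6)


def _stream(seed: int, label: int) -> np.random.Generator:
    """One independent substream per random quantity.

    Each quantity is drawn as a single frame-major array from its own
    stream, so extending n_frames never reshuffles earlier frames.
    """
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, label])))


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Parameters of the simulated walker and camera.

    Body proportions are in canonical units (shoulder width 2.0) and are
    mapped to pixels by ``px_per_unit`` (default 26 px/unit, i.e. a body of
    roughly 180 px at camera scale 1).  The camera records 1280x720 at
    25 fps; the walker strides at ~1 Hz.
    """

    n_frames: int = 150
    frame_rate: float = 25.0
    # canonical proportions (units)
    shoulder_width: float = 2.0
    hip_width: float = 1.4
    trunk_length: float = 3.0
    upper_arm: float = 1.4
    lower_arm: float = 1.3
    thigh: float = 1.8
    shank: float = 1.7
    px_per_unit: float = 26.0
    # gait
    arm_swing_amplitude_deg: float = 15.0
    leg_swing_amplitude_deg: float = 10.0
    swing_frequency_hz: float = 1.0
    profile: str = "CON"
    amplitude_cv: float | None = None       # default: from profile
    angle_jitter_sd_deg: float | None = None  # default: from profile
    # camera
    direction: str = "towards"
    scale_start: float = 1.0
    scale_end: float = 2.0
    scale_trajectory: tuple[float, ...] | None = None
    center_x: float = 640.0
    center_y: float = 250.0
    jitter_sd: float = 3.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.02
    confidence_mean: float = 0.89
    confidence_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for name in ("shoulder_width", "hip_width", "trunk_length", "upper_arm",
                     "lower_arm", "thigh", "shank", "px_per_unit", "frame_rate",
                     "swing_frequency_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("arm_swing_amplitude_deg", "leg_swing_amplitude_deg",
                     "jitter_sd", "noise_sd", "confidence_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.profile not in PROFILE_PARAMS:
            raise ValueError(f"profile must be one of {sorted(PROFILE_PARAMS)}")
        if self.direction not in ("towards", "away"):
            raise ValueError("direction must be 'towards' or 'away'")
        if self.scale_trajectory is not None:
            traj = tuple(float(s) for s in self.scale_trajectory)
            if len(traj) != self.n_frames or min(traj) <= 0:
                raise ValueError("scale_trajectory must hold n_frames positive factors")
            object.__setattr__(self, "scale_trajectory", traj)
        if self.scale_start <= 0 or self.scale_end <= 0:
            raise ValueError("scale endpoints must be positive")

    @property
    def resolved_amplitude_cv(self) -> float:
        return self.amplitude_cv if self.amplitude_cv is not None else PROFILE_PARAMS[self.profile][0]

    @property
    def resolved_angle_jitter_sd_deg(self) -> float:
        return (self.angle_jitter_sd_deg if self.angle_jitter_sd_deg is not None
                else PROFILE_PARAMS[self.profile][1])

    def scales(self) -> np.ndarray:
        if self.scale_trajectory is not None:
            return np.asarray(self.scale_trajectory, float)
        lo, hi = self.scale_start, self.scale_end
        ramp = np.linspace(lo, hi, self.n_frames)
        return ramp if self.direction == "towards" else ramp[::-1].copy()


@dataclass(frozen=True)
class SyntheticGaitTruth:
    """Ground truth of one simulated segment (all per-frame)."""

    canonical_x: np.ndarray
    canonical_y: np.ndarray
    applied_scales: np.ndarray
    applied_jitter: np.ndarray  # (n, 2)
    dropout_mask: np.ndarray    # (n, 17) bool


def make_walker(config: SyntheticGaitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Canonical body-frame pose sequence, (x, y) arrays of shape (n, 17).

    Pixels at camera scale 1; mid-shoulder at the origin, y increasing
    downward (image convention).  The torso is rigid; arms and legs swing
    sinusoidally in the coronal plane with per-cycle amplitudes and
    per-frame angle jitter set by the clinical profile.
    """
    c = config
    n = c.n_frames
    px = c.px_per_unit
    t = np.arange(n) / c.frame_rate
    phase = 2.0 * np.pi * c.swing_frequency_hz * t
    cycle = np.floor(c.swing_frequency_hz * t).astype(int)
    n_cycles = int(cycle.max()) + 1

    # per-cycle amplitude factors, 4 limbs: L arm, R arm, L leg, R leg
    fac = 1.0 + c.resolved_amplitude_cv * _stream(c.seed, _CYCLES).standard_normal(
        (n_cycles, 4))
    fac = np.maximum(fac, 0.0)[cycle]  # (n, 4)
    # per-frame within-cycle angle jitter (radians)
    eps = np.deg2rad(c.resolved_angle_jitter_sd_deg) * _stream(
        c.seed, _LIMB_JITTER).standard_normal((n, 4))

    arm_amp = np.deg2rad(c.arm_swing_amplitude_deg)
    leg_amp = np.deg2rad(c.leg_swing_amplitude_deg)
    # lateral swing angle from vertical-down, positive = outward
    th_arm_l = arm_amp * fac[:, 0] * np.sin(phase) + eps[:, 0]
    th_arm_r = arm_amp * fac[:, 1] * np.sin(phase + np.pi) + eps[:, 1]
    th_leg_l = leg_amp * fac[:, 2] * np.sin(phase + np.pi) + eps[:, 2]
    th_leg_r = leg_amp * fac[:, 3] * np.sin(phase) + eps[:, 3]

    x = np.zeros((n, 17))
    y = np.zeros((n, 17))

    sw, hw = c.shoulder_width / 2, c.hip_width / 2
    # head (static relative to shoulders); subject faces the camera, so the
    # subject's left appears at +x in the image
    head = {
        K.NOSE: (0.0, -0.9), K.LEFT_EYE: (0.18, -1.0), K.RIGHT_EYE: (-0.18, -1.0),
        K.LEFT_EAR: (0.35, -0.92), K.RIGHT_EAR: (-0.35, -0.92),
    }
    for k, (hx, hy) in head.items():
        x[:, k] = hx * px
        y[:, k] = hy * px
    x[:, K.LEFT_SHOULDER], x[:, K.RIGHT_SHOULDER] = sw * px, -sw * px
    x[:, K.LEFT_HIP], x[:, K.RIGHT_HIP] = hw * px, -hw * px
    y[:, K.LEFT_HIP] = y[:, K.RIGHT_HIP] = c.trunk_length * px

    def limb(root_k, mid_k, end_k, sign, theta, l1, l2, bend):
        # mid = root + l1*(sin, cos), end = mid + l2*(sin, cos) at a slightly
        # amplified angle (distal segments swing further)
        x[:, mid_k] = x[:, root_k] + sign * l1 * px * np.sin(theta)
        y[:, mid_k] = y[:, root_k] + l1 * px * np.cos(theta)
        x[:, end_k] = x[:, mid_k] + sign * l2 * px * np.sin(bend * theta)
        y[:, end_k] = y[:, mid_k] + l2 * px * np.cos(bend * theta)

    limb(K.LEFT_SHOULDER, K.LEFT_ELBOW, K.LEFT_WRIST, +1, th_arm_l,
         c.upper_arm, c.lower_arm, 1.3)
    limb(K.RIGHT_SHOULDER, K.RIGHT_ELBOW, K.RIGHT_WRIST, -1, th_arm_r,
         c.upper_arm, c.lower_arm, 1.3)
    limb(K.LEFT_HIP, K.LEFT_KNEE, K.LEFT_ANKLE, +1, th_leg_l,
         c.thigh, c.shank, 1.1)
    limb(K.RIGHT_HIP, K.RIGHT_KNEE, K.RIGHT_ANKLE, -1, th_leg_r,
         c.thigh, c.shank, 1.1)
    return x, y


def project_to_camera(
    canonical: tuple[np.ndarray, np.ndarray],
    config: SyntheticGaitConfig,
    participant_id: str = "sim",
    group: str | None = None,
    segment_label: str = "synthetic",
) -> tuple[GaitSegment, SyntheticGaitTruth]:
    """Apply camera scale, handheld jitter, keypoint noise, confidences and
    dropout to a canonical pose sequence."""
    c = config
    cx, cy = canonical
    n = cx.shape[0]
    scales = c.scales()

    jitter = c.jitter_sd * _stream(c.seed, _CAM_JITTER).standard_normal((n, 2))
    noise = c.noise_sd * _stream(c.seed, _KP_NOISE).standard_normal((n, 17, 2))
    conf = np.clip(
        c.confidence_mean + c.confidence_sd * _stream(c.seed, _CONFIDENCE).standard_normal((n, 17)),
        0.0, 1.0,
    )
    dropout = _stream(c.seed, _DROPOUT).uniform(size=(n, 17)) < c.dropout_rate
    conf[dropout] = 0.0

    x = cx * scales[:, None] + c.center_x + jitter[:, 0:1] + noise[:, :, 0]
    y = cy * scales[:, None] + c.center_y + jitter[:, 1:2] + noise[:, :, 1]

    segment = GaitSegment(
        frame_indices=np.arange(n),
        x=x, y=y, confidence=conf,
        participant_id=participant_id,
        group=group if group is not None else (c.profile),
        direction=c.direction,
        segment_label=segment_label,
    )
    truth = SyntheticGaitTruth(
        canonical_x=cx, canonical_y=cy, applied_scales=scales,
        applied_jitter=jitter, dropout_mask=dropout,
    )
    return segment, truth


def simulate_segment(config: SyntheticGaitConfig, participant_id: str = "sim",
                     segment_label: str = "synthetic"
                     ) -> tuple[GaitSegment, SyntheticGaitTruth]:
    """make_walker + project_to_camera in one call."""
    return project_to_camera(make_walker(config), config,
                             participant_id=participant_id,
                             segment_label=segment_label)


def segment_to_detections(segment: GaitSegment, track_id: int = 1) -> list[Detection]:
    """Express a segment as AlphaPose-style detections (one per frame)."""
    return [
        Detection(frame_index=int(segment.frame_indices[i]), track_id=track_id,
                  score=float(segment.confidence[i].mean()),
                  pose=Pose(frame_index=int(segment.frame_indices[i]),
                            x=segment.x[i], y=segment.y[i],
                            confidence=segment.confidence[i]))
        for i in range(segment.n_frames)
    ]
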