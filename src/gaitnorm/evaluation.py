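"""Evaluation metrics for normalization quality, and group statistics.

Two complementary metrics judge a normalization method:

* **Mean absolute angle error** — coronal-plane joint angles are a pure
  function of shape, so an ideal normalization leaves them untouched.  Four
  relative angles (elbows: wrist->elbow vs elbow->shoulder; knees: hip->knee
  vs knee->ankle) and eight absolute angles (the same limb vectors against
  the horizontal image axis) are compared before vs after normalization.
* **Mean variance of inter-keypoint distance** — the shoulder and hip
  distances are nearly rigid during frontal gait, so their residual variance
  measures nonphysiological scale/position variability a method failed to
  remove, while wrist and ankle distance variance carries genuine movement
  variability that a method must not flatten.

Group comparisons use the Mann-Whitney U test (segments as sampling units)
and the likelihood contrast before/after cleaning uses a paired t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .keypoints import (
    ABSOLUTE_ANGLE_DEFS,
    DISTANCE_PAIRS,
    RELATIVE_ANGLE_DEFS,
    Keypoint,
)
from .segment import GaitSegment

__all__ = [
    "absolute_angle",
    "relative_angle",
    "segment_angles",
    "angle_error",
    "pair_distance_series",
    "mean_distance_variance",
    "mann_whitney_u",
    "paired_t",
    "keypoint_dispersion",
    "EvaluationReport",
    "evaluate_methods",
]

ANGLE_NAMES = tuple(f"rel_{n}" for n in RELATIVE_ANGLE_DEFS) + tuple(
    f"abs_{n}" for n in ABSOLUTE_ANGLE_DEFS
)


def absolute_angle(v: np.ndarray) -> float:
    """Undirected angle (degrees, in [0, 180)) between a 2D vector and the
    horizontal axis."""
    v = np.asarray(v, float)
    if np.hypot(v[0], v[1]) == 0.0:
        raise ValueError("zero vector has no direction")
    return float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)


def relative_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 2D vectors in degrees, in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.hypot(*u), np.hypot(*v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero vector has no direction")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _vec(seg: GaitSegment, tail: Keypoint, head: Keypoint) -> tuple[np.ndarray, np.ndarray]:
    return seg.x[:, head] - seg.x[:, tail], seg.y[:, head] - seg.y[:, tail]


def segment_angles(segment: GaitSegment) -> pd.DataFrame:
    """Per-frame values of the 12 evaluation angles (degrees).

    Columns are the 4 relative angles (``rel_*``, in [0, 180]) followed by
    the 8 undirected absolute angles (``abs_*``, in [0, 180)).
    """
    cols: dict[str, np.ndarray] = {}
    for name, ((t1, h1), (t2, h2)) in RELATIVE_ANGLE_DEFS.items():
        ux, uy = _vec(segment, t1, h1)
        vx, vy = _vec(segment, t2, h2)
        dot = ux * vx + uy * vy
        norm = np.hypot(ux, uy) * np.hypot(vx, vy)
        with np.errstate(invalid="ignore"):
            cols[f"rel_{name}"] = np.degrees(np.arccos(np.clip(dot / norm, -1, 1)))
    for name, (tail, head) in ABSOLUTE_ANGLE_DEFS.items():
        vx, vy = _vec(segment, tail, head)
        cols[f"abs_{name}"] = np.degrees(np.arctan2(vy, vx)) % 180.0
    return pd.DataFrame(cols, index=segment.frame_indices)


def angle_error(before: GaitSegment, after: GaitSegment) -> pd.Series:
    """Mean absolute angle error (degrees) per angle, plus the overall mean.

    Segments must be frame-aligned.  Absolute angles are undirected, so
    their error is the minimal circular difference wrapped into [0, 90]
    (179 deg vs 1 deg is a 2 deg error, not 178); relative-angle errors are
    plain absolute differences in [0, 180].  Errors are averaged over
    frames; ``"overall"`` is the mean over the 12 angles.
    """
    if not np.array_equal(before.frame_indices, after.frame_indices):
        raise ValueError("segments are not frame-aligned")
    a = segment_angles(before)
    b = segment_angles(after)
    err = (a - b).abs()
    for col in err.columns:
        if col.startswith("abs_"):
            err[col] = np.minimum(err[col], 180.0 - err[col])
    out = err.mean(axis=0)
    out["overall"] = out[list(ANGLE_NAMES)].mean()
    return out


def pair_distance_series(segment: GaitSegment, pair: str) -> np.ndarray:
    """Per-frame Euclidean distance (pixels) between a bilateral pair
    (one of shoulders/wrists/hips/ankles)."""
    left, right = DISTANCE_PAIRS[pair]
    return np.hypot(segment.x[:, left] - segment.x[:, right],
                    segment.y[:, left] - segment.y[:, right])


def mean_distance_variance(segments: list[GaitSegment], pair: str,
                           group: str | None = None, ddof: int = 1) -> float:
    """Mean over segments of the per-segment variance (pixels^2) of a pair's
    distance series; optionally restricted to one participant group."""
    if group is not None:
        segments = [s for s in segments if s.group == group]
    variances = [
        float(np.var(pair_distance_series(s, pair), ddof=ddof))
        for s in segments
        if s.n_frames >= 2
    ]
    if not variances:
        raise ValueError("no usable segments")
    return float(np.mean(variances))


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, p).

    U is the rank-sum statistic of ``x`` (midranks for ties).  The p value
    is exact by enumeration for small tie-free samples (n_x + n_y <= 12),
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired-samples t test; returns (t, df, two-sided p).

    Raises for all-zero or zero-variance differences, where t is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = x - y
    if np.var(d, ddof=1) == 0.0:
        raise ValueError("degenerate test: differences have zero variance")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def keypoint_dispersion(segment: GaitSegment) -> pd.DataFrame:
    """Per-keypoint location spread over a segment, in pixels.

    Columns: SD of x, SD of y (n-1 denominator), and the RMS radius about
    the keypoint's own centroid.  After a good normalization each keypoint's
    cloud concentrates in a small region.
    """
    if segment.n_frames < 2:
        raise ValueError("need at least 2 frames")
    cx = segment.x.mean(axis=0)
    cy = segment.y.mean(axis=0)
    r2 = (segment.x - cx) ** 2 + (segment.y - cy) ** 2
    return pd.DataFrame(
        {
            "sd_x": segment.x.std(axis=0, ddof=1),
            "sd_y": segment.y.std(axis=0, ddof=1),
            "rms_radius": np.sqrt(r2.mean(axis=0)),
        },
        index=[k.name.lower() for k in Keypoint],
    )


@dataclass
class EvaluationReport:
    """Angle-error and distance-variance summaries per method, with group tests.

    ``angle_errors``: rows = methods, columns = the 12 angles + ``overall``.
    ``distance_variance``: MultiIndex (method incl. ``original``, group incl.
    ``all``) x the four pairs.  ``test_results``: one row per comparison with
    the U statistic and p value.  Aggregation order: mean over frames, then
    over segments, then over the angle set.
    """

    angle_errors: pd.DataFrame
    distance_variance: pd.DataFrame
    test_results: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "angle_errors": self.angle_errors.to_dict(orient="index"),
            "distance_variance": {
                f"{m}|{g}": row.to_dict()
                for (m, g), row in self.distance_variance.iterrows()
            },
            "test_results": self.test_results.to_dict(orient="records"),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationReport":
        dv = pd.DataFrame.from_dict(doc["distance_variance"], orient="index")
        dv.index = pd.MultiIndex.from_tuples(
            [tuple(k.split("|")) for k in dv.index], names=["method", "group"])
        return cls(
            angle_errors=pd.DataFrame.from_dict(doc["angle_errors"], orient="index"),
            distance_variance=dv,
            test_results=pd.DataFrame(doc["test_results"]),
            metadata=doc.get("metadata", {}),
        )


def evaluate_methods(
    segments: list[GaitSegment],
    methods=None,
    offset=None,
    on_degenerate: str = "error",
    groups: tuple[str, ...] = ("EOA", "DCD", "CON"),
    test_pairs: tuple[str, ...] = ("wrists", "ankles"),
    holm: bool = False,
) -> EvaluationReport:
    """Run the full method comparison on a collection of (cleaned) segments.

    For every normalization method: normalize each segment, accumulate the
    per-angle error (mean over frames, then over segments) and the mean
    distance variance per pair (overall and per group), then Mann-Whitney
    tests between all group pairs on wrist/ankle per-segment variances.
    No multiple-testing correction by default; ``holm=True`` applies Holm's
    step-down adjustment to the reported p values.
    """
    from .normalization import NormalizationMethod, RecenterOffset, normalize_segment

    methods = [NormalizationMethod(m) for m in (methods or list(NormalizationMethod))]
    offset = offset or RecenterOffset()

    present_groups = [g for g in groups if any(s.group == g for s in segments)]
    angle_rows: dict[str, pd.Series] = {}
    dv_rows: dict[tuple[str, str], dict[str, float]] = {}
    tests: list[dict] = []

    def _dv_block(label: str, segs: list[GaitSegment]) -> None:
        dv_rows[(label, "all")] = {
            p: mean_distance_variance(segs, p) for p in DISTANCE_PAIRS
        }
        for g in present_groups:
            dv_rows[(label, g)] = {
                p: mean_distance_variance(segs, p, group=g) for p in DISTANCE_PAIRS
            }

    _dv_block("original", segments)
    for method in methods:
        normed = [
            normalize_segment(s, method, offset, on_degenerate=on_degenerate)
            for s in segments
        ]
        errs = pd.DataFrame(
            [angle_error(s, ns) for s, ns in zip(segments, normed)
             if np.array_equal(s.frame_indices, ns.frame_indices)]
        )
        angle_rows[method.value] = errs.mean(axis=0)
        _dv_block(method.value, normed)
        for pair_name in test_pairs:
            for i, ga in enumerate(present_groups):
                for gb in present_groups[i + 1:]:
                    va = [np.var(pair_distance_series(s, pair_name), ddof=1)
                          for s in normed if s.group == ga]
                    vb = [np.var(pair_distance_series(s, pair_name), ddof=1)
                          for s in normed if s.group == gb]
                    if not va or not vb:
                        continue
                    u, p = mann_whitney_u(va, vb)
                    tests.append({
                        "method": method.value, "pair": pair_name,
                        "group_a": ga, "group_b": gb,
                        "n_a": len(va), "n_b": len(vb), "U": u, "p": p,
                    })

    test_df = pd.DataFrame(tests)
    if holm and len(test_df):
        order = np.argsort(test_df["p"].to_numpy())
        m = len(test_df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * test_df["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        test_df["p_holm"] = adj

    dv = pd.DataFrame.from_dict(dv_rows, orient="index")
    dv.index = pd.MultiIndex.from_tuples(dv.index, names=["method", "group"])
    return EvaluationReport(
        angle_errors=pd.DataFrame(angle_rows).T,
        distance_variance=dv,
        test_results=test_df,
        metadata={
            "n_segments": len(segments),
            "methods": [m.value for m in methods],
            "aggregation": "frames -> segments -> angle set",
            "variance_ddof": 1,
            "sampling_unit": "segment",
            "holm": holm,
        },
    )
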