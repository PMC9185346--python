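"""Reading and writing keypoint files.

Two formats are handled:

* the AlphaPose COCO-17 result JSON (both the flat detection array and the
  per-image grouped dialect, auto-detected from the top-level structure), and
* this package's internal segment JSON — explicit keypoint names, per-frame
  arrays and a versioned metadata header — which round-trips bit-exactly.

Coordinates are never altered on read: no rounding, no axis flip, pixel
units untouched.
"""

from __future__ import annotations

import json
import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .keypoints import KEYPOINT_NAMES, N_KEYPOINTS
from .segment import GaitSegment, Pose

__all__ = [
    "Detection",
    "read_alphapose",
    "write_alphapose",
    "select_track",
    "assemble_segment",
    "read_segment",
    "write_segment",
    "read_annotations",
    "extract_annotated_segments",
]

logger = logging.getLogger(__name__)

SEGMENT_FORMAT = "gaitnorm-segment"
SEGMENT_VERSION = 1


class Detection(NamedTuple):
    frame_index: int
    track_id: int
    score: float
    pose: Pose


class AlphaPoseFormatError(ValueError):
    """Raised for malformed AlphaPose records."""


_NUM_RE = re.compile(r"(\d+)")


def _frame_index_of(image_id: object, order: dict[str, int]) -> int:
    """Map an AlphaPose ``image_id`` to a frame index.

    Integer ids pass through; string ids use the numeric part of the filename
    stem (AlphaPose emits image filenames such as ``"137.jpg"``), falling back
    to natural-sort rank for non-numeric stems.
    """
    if isinstance(image_id, int):
        return image_id
    stem = Path(str(image_id)).stem
    m = _NUM_RE.search(stem)
    if m:
        return int(m.group(1))
    return order[str(image_id)]


def _natural_key(s: str) -> tuple:
    return tuple(int(t) if t.isdigit() else t for t in _NUM_RE.split(Path(s).stem))


def _pose_from_keypoints(keypoints: Sequence[float], frame_index: int, where: str) -> Pose:
    kp = np.asarray(keypoints, dtype=float)
    if kp.shape != (3 * N_KEYPOINTS,):
        raise AlphaPoseFormatError(
            f"record {where}: keypoint list has length {kp.size}, expected 51"
        )
    kp = kp.reshape(N_KEYPOINTS, 3)
    return Pose(frame_index=frame_index, x=kp[:, 0], y=kp[:, 1],
                confidence=np.clip(kp[:, 2], 0.0, 1.0))


def read_alphapose(path: str | Path) -> list[Detection]:
    """Read an AlphaPose COCO-17 result file into per-detection records.

    Supports the flat detection array (objects with ``image_id``,
    ``keypoints``, ``score``, ``idx``) and the per-image grouped dialect
    (objects with ``image_id`` and a ``people`` list); the dialect is
    auto-detected from the first element.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise AlphaPoseFormatError(f"{path}: top level must be a JSON array")
    if not data:
        return []

    # natural-sort rank fallback for non-numeric image ids
    ids = [str(rec.get("image_id", i)) for i, rec in enumerate(data)]
    order = {s: i for i, s in enumerate(sorted(set(ids), key=_natural_key))}

    detections: list[Detection] = []
    grouped = isinstance(data[0], dict) and "people" in data[0]
    for i, rec in enumerate(data):
        if not isinstance(rec, dict):
            raise AlphaPoseFormatError(f"{path}: record {i} is not an object")
        frame = _frame_index_of(rec.get("image_id", i), order)
        people = rec["people"] if grouped else [rec]
        for j, person in enumerate(people):
            if "keypoints" not in person:
                raise AlphaPoseFormatError(f"{path}: record {i}/{j} lacks 'keypoints'")
            pose = _pose_from_keypoints(person["keypoints"], frame, f"{i}/{j} in {path.name}")
            detections.append(
                Detection(
                    frame_index=frame,
                    track_id=int(person.get("idx", 0)),
                    score=float(person.get("score", 0.0)),
                    pose=pose,
                )
            )
    return detections


def write_alphapose(detections: Iterable[Detection], path: str | Path,
                    grouped: bool = False) -> None:
    """Write detections in the AlphaPose flat (default) or grouped dialect."""
    recs = []
    for d in detections:
        kp = np.column_stack([d.pose.x, d.pose.y, d.pose.confidence]).ravel()
        recs.append(
            {
                "image_id": f"{d.frame_index}.jpg",
                "category_id": 1,
                "keypoints": kp.tolist(),
                "score": d.score,
                "idx": d.track_id,
            }
        )
    if grouped:
        by_image: dict[str, list[dict]] = defaultdict(list)
        for rec in recs:
            image_id = rec.pop("image_id")
            by_image[image_id].append(rec)
        out = [{"image_id": k, "people": v} for k, v in by_image.items()]
    else:
        out = recs
    with open(path, "w") as fh:
        json.dump(out, fh)


def select_track(detections: Sequence[Detection],
                 track_id: int | str = "auto") -> list[tuple[int, Pose]]:
    """Keep detections of one track, one pose per frame.

    With ``"auto"`` the track covering the most frames wins (tie broken by
    highest mean detection score).  Duplicate detections of the same track in
    one frame keep the higher-score one (with a warning).
    """
    if not detections:
        raise ValueError("no detections to select a track from")
    tracks: dict[int, list[Detection]] = defaultdict(list)
    for d in detections:
        tracks[d.track_id].append(d)
    if track_id == "auto":
        track_id = max(
            tracks,
            key=lambda t: (len({d.frame_index for d in tracks[t]}),
                           float(np.mean([d.score for d in tracks[t]]))),
        )
    elif track_id not in tracks:
        raise KeyError(
            f"track {track_id} not present; available tracks: {sorted(tracks)}"
        )
    best: dict[int, Detection] = {}
    for d in tracks[track_id]:
        prev = best.get(d.frame_index)
        if prev is not None:
            logger.warning(
                "duplicate detection for track %s in frame %d; keeping higher score",
                track_id, d.frame_index,
            )
            if d.score <= prev.score:
                continue
        best[d.frame_index] = d
    return [(f, best[f].pose) for f in sorted(best)]


def assemble_segment(frames: Sequence[tuple[int, Pose]], participant_id: str,
                     group: str, direction: str, segment_label: str = "") -> GaitSegment:
    """Build a GaitSegment from (frame_index, Pose) pairs plus annotation."""
    if len(frames) < 2:
        raise ValueError("segment too short: need at least 2 frames")
    poses = [
        Pose(frame_index=f, x=p.x, y=p.y, confidence=p.confidence)
        for f, p in frames
    ]
    return GaitSegment.from_poses(
        poses, participant_id=participant_id, group=group,
        direction=direction, segment_label=segment_label,
    )


# ---------------------------------------------------------------------------
# internal segment format


def write_segment(segment: GaitSegment, path: str | Path) -> None:
    doc = {
        "format": SEGMENT_FORMAT,
        "version": SEGMENT_VERSION,
        **segment.metadata(),
        "keypoint_names": list(KEYPOINT_NAMES),
        "frames": [
            {
                "frame_index": int(segment.frame_indices[i]),
                "x": segment.x[i].tolist(),
                "y": segment.y[i].tolist(),
                "confidence": segment.confidence[i].tolist(),
            }
            for i in range(segment.n_frames)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_segment(path: str | Path) -> GaitSegment:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != SEGMENT_FORMAT:
        raise ValueError(f"{path}: not a {SEGMENT_FORMAT} file")
    if doc.get("keypoint_names") != list(KEYPOINT_NAMES):
        raise ValueError(f"{path}: unexpected keypoint layout")
    frames = doc["frames"]
    return GaitSegment(
        frame_indices=np.array([f["frame_index"] for f in frames], dtype=int),
        x=np.array([f["x"] for f in frames], dtype=float),
        y=np.array([f["y"] for f in frames], dtype=float),
        confidence=np.array([f["confidence"] for f in frames], dtype=float),
        participant_id=doc.get("participant_id", ""),
        group=doc.get("group", "CON"),
        direction=doc.get("direction", "towards"),
        segment_label=doc.get("segment_label", ""),
    )


# ---------------------------------------------------------------------------
# annotation table

ANNOTATION_COLUMNS = ["participant_id", "group", "direction", "segment_label",
                      "start_frame", "end_frame"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the segment-annotation CSV (participant, group, direction, label,
    inclusive frame range)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "segment_label": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    return df


def extract_annotated_segments(frames: Sequence[tuple[int, Pose]],
                               annotations: pd.DataFrame) -> list[GaitSegment]:
    """Slice a tracked pose stream into the annotated gait segments."""
    segments = []
    for _, row in annotations.iterrows():
        sel = [(f, p) for f, p in frames
               if row.start_frame <= f <= row.end_frame]
        if len(sel) < 2:
            raise ValueError(
                f"segment too short: annotation {row.segment_label!r} covers "
                f"{len(sel)} frames"
            )
        segments.append(
            assemble_segment(sel, participant_id=row.participant_id,
                             group=row.group, direction=row.direction,
                             segment_label=row.segment_label)
        )
    return segments
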