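"""Reading, validation and segmentation of 2D body-keypoint tracks.

This module fixes the coordinate and indexing conventions used by every
downstream stage:

* image coordinates in pixels, ``x`` rightward, ``y`` downward;
* 0-based, strictly increasing frame indices;
* keypoints in the standard COCO-17 order (nose, eyes, ears, shoulders,
  elbows, wrists, hips, knees, ankles).

Two on-disk layouts are supported.  JSON: a list of track objects
``{"video_id", "fps", "frames": [{"frame_index", "bbox": [x, y, w, h],
"keypoints": [[x, y, c] * 17]}]}``.  CSV: one row per frame with columns
``video_id, fps, frame_index, bbox_x, bbox_y, bbox_w, bbox_h`` followed by
``kpt{i}_x, kpt{i}_y, kpt{i}_c`` for ``i`` in 0..16.  Instance metadata lives
in a sidecar CSV with columns ``video_id, subject_id, task, posture,
load_kg, onset_frame, offset_frame``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_KEYPOINTS = 17

COCO_KEYPOINT_NAMES = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

COCO_INDEX = {name: i for i, name in enumerate(COCO_KEYPOINT_NAMES)}

TASKS = ("lift", "lower")
POSTURES = ("mid-shin", "knuckle", "shoulder")


class PoseIOError(ValueError):
    """Base class for validation failures in this module."""


class SchemaError(PoseIOError):
    """A file or frame does not conform to the documented schema."""


class GapError(PoseIOError):
    """A low-confidence gap cannot be interpolated."""

    def __init__(self, message: str, gaps: list[tuple[str, int, int]] | None = None):
        super().__init__(message)
        #: list of (joint_name, first_frame, last_frame) spans left unusable
        self.gaps = gaps or []


@dataclass(frozen=True)
class Keypoint:
    """A single 2D keypoint with detector confidence in [0, 1]."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise SchemaError(f"keypoint coordinates must be finite, got ({self.x}, {self.y})")
        if not (0.0 <= self.confidence <= 1.0):
            raise SchemaError(f"keypoint confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class PoseFrame:
    """One video frame: 17 COCO keypoints plus a person bounding box."""

    frame_index: int
    keypoints: tuple[Keypoint, ...]
    bbox: tuple[float, float, float, float]  # (x_min, y_min, width, height)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise SchemaError(f"frame_index must be >= 0, got {self.frame_index}")
        if len(self.keypoints) != N_KEYPOINTS:
            raise SchemaError(
                f"frame {self.frame_index}: expected {N_KEYPOINTS} keypoints, "
                f"got {len(self.keypoints)}"
            )
        x, y, w, h = self.bbox
        if not all(math.isfinite(v) for v in self.bbox):
            raise SchemaError(f"frame {self.frame_index}: bbox must be finite, got {self.bbox}")
        if w <= 0 or h <= 0:
            raise SchemaError(
                f"frame {self.frame_index}: bbox width/height must be positive, got {self.bbox}"
            )


@dataclass(frozen=True)
class PoseTrack:
    """A time-ordered sequence of PoseFrames for one person in one video."""

    frames: tuple[PoseFrame, ...]
    fps: float
    video_id: str

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SchemaError(f"fps must be positive, got {self.fps}")
        if len(self.frames) < 3:
            raise SchemaError(
                f"track {self.video_id!r}: at least 3 frames are required "
                f"(central differences), got {len(self.frames)}"
            )
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SchemaError(f"track {self.video_id!r}: frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def keypoint_array(self) -> np.ndarray:
        """Return keypoints as a (T, 17, 3) float array of (x, y, confidence)."""
        return np.array(
            [[(k.x, k.y, k.confidence) for k in f.keypoints] for f in self.frames],
            dtype=float,
        )

    def bbox_array(self) -> np.ndarray:
        """Return bounding boxes as a (T, 4) float array of (x, y, w, h)."""
        return np.array([f.bbox for f in self.frames], dtype=float)


@dataclass(frozen=True)
class LiftRecord:
    """One annotated lifting or lowering instance, clipped from a track."""

    track: PoseTrack
    subject_id: str
    task: str
    posture: str
    load_kg: float
    onset_frame: int
    offset_frame: int

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise SchemaError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.posture not in POSTURES:
            raise SchemaError(f"posture must be one of {POSTURES}, got {self.posture!r}")
        if self.load_kg <= 0:
            raise SchemaError(f"load_kg must be positive, got {self.load_kg}")
        if self.onset_frame >= self.offset_frame:
            raise SchemaError(
                f"onset must precede offset, got ({self.onset_frame}, {self.offset_frame})"
            )


# ---------------------------------------------------------------------------
# construction helpers


def track_from_arrays(
    keypoints: np.ndarray,
    bboxes: np.ndarray | None,
    fps: float,
    video_id: str,
    frame_indices: Sequence[int] | None = None,
) -> PoseTrack:
    """Build a validated PoseTrack from a (T, 17, 3) keypoint array.

    When ``bboxes`` is None, a tight box over keypoints with confidence
    >= 0.5 is computed per frame (falling back to all keypoints if none
    clears the bar), so sources without detector boxes still work.
    """
    keypoints = np.asarray(keypoints, dtype=float)
    if keypoints.ndim != 3 or keypoints.shape[1:] != (N_KEYPOINTS, 3):
        raise SchemaError(f"expected keypoints of shape (T, 17, 3), got {keypoints.shape}")
    T = keypoints.shape[0]
    if frame_indices is None:
        frame_indices = range(T)
    if bboxes is None:
        bboxes = np.empty((T, 4))
        for t in range(T):
            conf = keypoints[t, :, 2]
            sel = conf >= 0.5
            pts = keypoints[t, sel, :2] if sel.any() else keypoints[t, :, :2]
            lo = pts.min(axis=0)
            hi = pts.max(axis=0)
            size = np.maximum(hi - lo, 1.0)
            bboxes[t] = (lo[0], lo[1], size[0], size[1])
    else:
        bboxes = np.asarray(bboxes, dtype=float)
    frames = tuple(
        PoseFrame(
            frame_index=int(fi),
            keypoints=tuple(Keypoint(*keypoints[t, j]) for j in range(N_KEYPOINTS)),
            bbox=tuple(bboxes[t]),
        )
        for t, fi in enumerate(frame_indices)
    )
    return PoseTrack(frames=frames, fps=float(fps), video_id=str(video_id))


# ---------------------------------------------------------------------------
# reading / writing


def _track_to_obj(track: PoseTrack) -> dict:
    return {
        "video_id": track.video_id,
        "fps": track.fps,
        "frames": [
            {
                "frame_index": f.frame_index,
                "bbox": list(f.bbox),
                "keypoints": [[k.x, k.y, k.confidence] for k in f.keypoints],
            }
            for f in track.frames
        ],
    }


def _track_from_obj(obj: dict, source: str) -> PoseTrack:
    try:
        video_id = str(obj["video_id"])
        fps = float(obj["fps"])
        raw_frames = obj["frames"]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{source}: missing required field {exc}") from exc
    frames = []
    for rf in raw_frames:
        try:
            kpts = rf["keypoints"]
            frame = PoseFrame(
                frame_index=int(rf["frame_index"]),
                keypoints=tuple(Keypoint(float(x), float(y), float(c)) for x, y, c in kpts),
                bbox=tuple(float(v) for v in rf["bbox"]),
            )
        except PoseIOError as exc:
            raise SchemaError(f"{source}, track {video_id!r}: {exc}") from exc
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{source}, track {video_id!r}: malformed frame ({exc})") from exc
        frames.append(frame)
    return PoseTrack(frames=tuple(frames), fps=fps, video_id=video_id)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("json", "csv"):
            raise ValueError(f"format must be 'json' or 'csv', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def read_pose_tracks(path: str | Path, format: str | None = None) -> list[PoseTrack]:
    """Read and validate pose tracks from a JSON or CSV file.

    Malformed frames raise :class:`SchemaError` naming the offending track
    and frame; nothing is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "json":
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = [data]
        return [_track_from_obj(obj, str(path)) for obj in data]
    # CSV
    df = pd.read_csv(path)
    required = ["video_id", "fps", "frame_index", "bbox_x", "bbox_y", "bbox_w", "bbox_h"]
    kpt_cols = [f"kpt{i}_{ax}" for i in range(N_KEYPOINTS) for ax in ("x", "y", "c")]
    missing = [c for c in required + kpt_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing[:5]}{'...' if len(missing) > 5 else ''}")
    tracks = []
    for video_id, group in df.groupby("video_id", sort=False):
        kpts = group[kpt_cols].to_numpy(dtype=float).reshape(len(group), N_KEYPOINTS, 3)
        bboxes = group[["bbox_x", "bbox_y", "bbox_w", "bbox_h"]].to_numpy(dtype=float)
        try:
            tracks.append(
                track_from_arrays(
                    kpts,
                    bboxes,
                    fps=float(group["fps"].iloc[0]),
                    video_id=str(video_id),
                    frame_indices=group["frame_index"].astype(int).tolist(),
                )
            )
        except PoseIOError as exc:
            raise SchemaError(f"{path}, track {video_id!r}: {exc}") from exc
    return tracks


def write_pose_tracks(tracks: Iterable[PoseTrack], path: str | Path, format: str | None = None) -> None:
    """Write tracks to JSON or CSV in the documented schema."""
    path = Path(path)
    fmt = _infer_format(path, format)
    tracks = list(tracks)
    if fmt == "json":
        path.write_text(json.dumps([_track_to_obj(t) for t in tracks], indent=1))
        return
    rows = []
    for t in tracks:
        for f in t.frames:
            row = {
                "video_id": t.video_id,
                "fps": t.fps,
                "frame_index": f.frame_index,
                "bbox_x": f.bbox[0],
                "bbox_y": f.bbox[1],
                "bbox_w": f.bbox[2],
                "bbox_h": f.bbox[3],
            }
            for i, k in enumerate(f.keypoints):
                row[f"kpt{i}_x"] = k.x
                row[f"kpt{i}_y"] = k.y
                row[f"kpt{i}_c"] = k.confidence
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_instance_metadata(path: str | Path) -> pd.DataFrame:
    """Read the instance-metadata sidecar CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = ["video_id", "subject_id", "task", "posture", "load_kg", "onset_frame", "offset_frame"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: metadata is missing columns {missing}")
    return df


def write_instance_metadata(records: Iterable[LiftRecord], path: str | Path) -> None:
    rows = [
        {
            "video_id": r.track.video_id,
            "subject_id": r.subject_id,
            "task": r.task,
            "posture": r.posture,
            "load_kg": r.load_kg,
            "onset_frame": r.onset_frame,
            "offset_frame": r.offset_frame,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# segmentation


def clip_instance(
    track: PoseTrack,
    onset: int,
    offset: int,
    *,
    subject_id: str,
    task: str,
    posture: str,
    load_kg: float,
) -> LiftRecord:
    """Clip a track to one annotated instance, frames [onset, offset] inclusive."""
    first = track.frames[0].frame_index
    last = track.frames[-1].frame_index
    if onset >= offset:
        raise PoseIOError(f"onset must precede offset, got ({onset}, {offset})")
    if onset < first or offset > last:
        raise PoseIOError(
            f"clip range [{onset}, {offset}] outside track range [{first}, {last}]"
        )
    frames = tuple(f for f in track.frames if onset <= f.frame_index <= offset)
    clipped = PoseTrack(frames=frames, fps=track.fps, video_id=track.video_id)
    return LiftRecord(
        track=clipped,
        subject_id=subject_id,
        task=task,
        posture=posture,
        load_kg=load_kg,
        onset_frame=onset,
        offset_frame=offset,
    )


def build_records(tracks: Sequence[PoseTrack], metadata: pd.DataFrame) -> list[LiftRecord]:
    """Join tracks with the metadata sidecar and clip each instance."""
    by_id = {t.video_id: t for t in tracks}
    records = []
    for row in metadata.itertuples(index=False):
        if row.video_id not in by_id:
            raise PoseIOError(f"metadata references unknown video_id {row.video_id!r}")
        records.append(
            clip_instance(
                by_id[row.video_id],
                int(row.onset_frame),
                int(row.offset_frame),
                subject_id=str(row.subject_id),
                task=str(row.task),
                posture=str(row.posture),
                load_kg=float(row.load_kg),
            )
        )
    return records


# ---------------------------------------------------------------------------
# gap interpolation


def interpolate_gaps(
    track: PoseTrack, conf_threshold: float = 0.3, max_gap: int = 5
) -> PoseTrack:
    """Fill short low-confidence dropouts by linear interpolation.

    A keypoint with confidence below ``conf_threshold`` is replaced by the
    linear interpolation between its nearest confident neighbours in time,
    provided the gap spans at most ``max_gap`` frames; interpolated points
    carry confidence exactly ``conf_threshold`` (which makes the operation
    idempotent).  Longer gaps, or gaps touching the track boundary, raise
    :class:`GapError` listing every unusable joint/frame span.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    kpts = track.keypoint_array()  # (T, 17, 3)
    T = kpts.shape[0]
    bad: list[tuple[str, int, int]] = []
    for j in range(N_KEYPOINTS):
        low = kpts[:, j, 2] < conf_threshold
        if not low.any():
            continue
        t = 0
        while t < T:
            if not low[t]:
                t += 1
                continue
            start = t
            while t < T and low[t]:
                t += 1
            end = t - 1  # inclusive
            name = COCO_KEYPOINT_NAMES[j]
            if start == 0 or end == T - 1:
                bad.append((name, start, end))
            elif end - start + 1 > max_gap:
                bad.append((name, start, end))
            else:
                left, right = start - 1, end + 1
                for u in range(start, end + 1):
                    w = (u - left) / (right - left)
                    kpts[u, j, :2] = (1 - w) * kpts[left, j, :2] + w * kpts[right, j, :2]
                    kpts[u, j, 2] = conf_threshold
    if bad:
        spans = "; ".join(f"{n}: frames {a}-{b}" for n, a, b in bad)
        raise GapError(f"unusable low-confidence gaps ({spans})", gaps=bad)
    return track_from_arrays(
        kpts,
        track.bbox_array(),
        fps=track.fps,
        video_id=track.video_id,
        frame_indices=[f.frame_index for f in track.frames],
    )


def interpolate_record(record: LiftRecord, conf_threshold: float = 0.3, max_gap: int = 5) -> LiftRecord:
    """Apply :func:`interpolate_gaps` to the track inside a LiftRecord."""
    return replace(record, track=interpolate_gaps(record.track, conf_threshold, max_gap))
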