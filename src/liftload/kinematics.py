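"""Sagittal-plane kinematic features from a clipped keypoint track.

A lifting instance viewed from the side exposes one body side; seven joints
(head, shoulder, elbow, wrist, hip, knee, ankle) are enough to characterise
the motion.  Each frame is summarised by a 47-dimensional feature vector
with fixed column layout

    [ r (14) | ang (5) | v (14) | a (14) ]

where ``r`` holds bounding-box-normalised joint positions, ``ang`` five
unsigned inter-segment angles in radians, and ``v``/``a`` finite-difference
velocities and accelerations of ``r`` in per-frame units (the sequence fps
is kept as metadata so per-second units are recoverable).

The head is represented by the COCO nose keypoint: COCO-17 has no explicit
head or neck landmark, and the nose is the most stable proxy in side view.
Angles are the unsigned interior angle at the shared joint, in [0, pi],
which makes them exactly invariant to the horizontal mirror used for
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np

from .pose_io import COCO_INDEX, LiftRecord, PoseTrack

if TYPE_CHECKING:  # pragma: no cover
    from .training_eval import LoadCategory

#: order of the seven sagittal joints everywhere in this package
SAGITTAL_JOINT_ORDER = ("head", "shoulder", "elbow", "wrist", "hip", "knee", "ankle")

#: the six side-specific limb joints used for side selection
_LIMB_JOINTS = ("shoulder", "elbow", "wrist", "hip", "knee", "ankle")

N_FEATURES = 47
POS = slice(0, 14)
ANG = slice(14, 19)
VEL = slice(19, 33)
ACC = slice(33, 47)

#: sign mask implementing the horizontal mirror in feature space:
#: -1 on the x columns of the r, v, a slices, +1 elsewhere
FLIP_SIGN = np.ones(N_FEATURES)
for _start in (POS.start, VEL.start, ACC.start):
    FLIP_SIGN[_start:_start + 14:2] = -1.0

# angle definitions as (endpoint_a, vertex, endpoint_b) indices into
# SAGITTAL_JOINT_ORDER; the angle is between segments vertex->a and vertex->b
_ANGLE_DEFS = (
    (0, 1, 2),  # head-shoulder vs shoulder-elbow, at the shoulder
    (1, 2, 3),  # shoulder-elbow vs elbow-wrist, at the elbow
    (2, 1, 4),  # shoulder-elbow vs shoulder-hip, at the shoulder
    (1, 4, 5),  # shoulder-hip vs hip-knee, at the hip
    (4, 5, 6),  # hip-knee vs knee-ankle, at the knee
)

_SEGMENT_EPS = 1e-6


class KinematicsError(ValueError):
    """Raised when a track cannot be converted to features."""


@dataclass(frozen=True)
class SagittalJoints:
    """Pixel trajectories of the seven sagittal joints of one body side."""

    side: str  # "left" or "right"
    positions: np.ndarray  # (T, 7, 2) pixels, SAGITTAL_JOINT_ORDER
    bboxes: np.ndarray  # (T, 4) pixels (x, y, w, h)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise KinematicsError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.positions.ndim != 3 or self.positions.shape[1:] != (7, 2):
            raise KinematicsError(f"positions must be (T, 7, 2), got {self.positions.shape}")
        if self.positions.shape[0] < 3:
            raise KinematicsError("at least 3 frames required")
        if self.bboxes.shape != (self.positions.shape[0], 4):
            raise KinematicsError("bboxes must be (T, 4) matching positions")


@dataclass(frozen=True)
class FeatureSequence:
    """T x 47 kinematic feature matrix with the documented slice layout."""

    values: np.ndarray  # (T, 47)
    fps: float

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise KinematicsError(f"feature width must be {N_FEATURES}, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise KinematicsError("feature values must be finite")
        if self.fps <= 0:
            raise KinematicsError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class LiftInstance:
    """A feature sequence plus its label and study metadata.

    ``label`` is normally consistent with ``load_kg`` under
    ``training_eval.categorize_load``; use
    ``training_eval.validate_instance_label`` to check.  Construction does
    not enforce it so that label-permutation control experiments remain
    expressible.
    """

    features: FeatureSequence
    label: "Optional[LoadCategory]"
    subject_id: str
    task: str
    posture: str
    load_kg: float


# ---------------------------------------------------------------------------
# joint selection


def _side_indices(side: str) -> list[int]:
    return [COCO_INDEX[f"{side}_{name}"] for name in _LIMB_JOINTS]


def select_side(track: PoseTrack, conf_threshold: float = 0.3) -> str:
    """Pick the visible body side by mean limb-keypoint confidence.

    Ties break toward "right".  If neither side has any keypoint at or above
    ``conf_threshold`` in any frame, the track is unusable.
    """
    kpts = track.keypoint_array()
    conf = {s: kpts[:, _side_indices(s), 2] for s in ("left", "right")}
    if all((c < conf_threshold).all() for c in conf.values()):
        raise KinematicsError(
            f"track {track.video_id!r}: both sides entirely below confidence "
            f"{conf_threshold}"
        )
    if conf["left"].mean() > conf["right"].mean():
        return "left"
    return "right"


def extract_sagittal_joints(
    track: PoseTrack, side: str, missing_threshold: float = 0.05
) -> SagittalJoints:
    """Pull the 7-joint sagittal trajectory (head = nose) for one side."""
    if side not in ("left", "right"):
        raise KinematicsError(f"side must be 'left' or 'right', got {side!r}")
    kpts = track.keypoint_array()
    indices = [COCO_INDEX["nose"]] + [COCO_INDEX[f"{side}_{n}"] for n in _LIMB_JOINTS]
    for name, j in zip(SAGITTAL_JOINT_ORDER, indices):
        if (kpts[:, j, 2] < missing_threshold).all():
            raise KinematicsError(
                f"track {track.video_id!r}: required joint {name!r} is missing "
                f"in every frame"
            )
    return SagittalJoints(
        side=side,
        positions=kpts[:, indices, :2].copy(),
        bboxes=track.bbox_array(),
    )


# ---------------------------------------------------------------------------
# features


def normalize_positions(joints: SagittalJoints) -> np.ndarray:
    """Normalise joint positions to a (T, 14) unitless matrix.

    Positions are re-centred on the per-frame bounding-box centre and scaled
    by the single maximum box height observed across the sequence, removing
    subject height and camera distance while keeping per-frame translation
    of the body within the box.
    """
    heights = joints.bboxes[:, 3]
    if (heights <= 0).any():
        raise KinematicsError("all bbox heights must be positive")
    centers = joints.bboxes[:, :2] + joints.bboxes[:, 2:] / 2.0
    h_max = heights.max()
    r = (joints.positions - centers[:, None, :]) / h_max
    return r.reshape(len(heights), 14)


def compute_angles(joints: SagittalJoints) -> np.ndarray:
    """Five unsigned inter-segment angles per frame, each in [0, pi].

    Each angle is arccos of the clamped normalised dot product of the two
    vectors from the shared joint to the segment endpoints.  Frames where a
    segment degenerates below 1e-6 pixels carry the previous frame's angle
    forward; a degenerate first frame (no prior valid value) is an error.
    """
    p = joints.positions
    T = p.shape[0]
    ang = np.empty((T, 5))
    for col, (a, vertex, b) in enumerate(_ANGLE_DEFS):
        u = p[:, a] - p[:, vertex]
        w = p[:, b] - p[:, vertex]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        valid = (nu >= _SEGMENT_EPS) & (nw >= _SEGMENT_EPS)
        if not valid[0]:
            raise KinematicsError(
                f"degenerate segment at frame 0 for angle {col + 1} "
                f"({SAGITTAL_JOINT_ORDER[a]}-{SAGITTAL_JOINT_ORDER[vertex]}-"
                f"{SAGITTAL_JOINT_ORDER[b]})"
            )
        denom = np.where(valid, nu * nw, 1.0)
        cosang = np.clip((u * w).sum(axis=1) / denom, -1.0, 1.0)
        col_vals = np.arccos(cosang)
        # carry the previous valid angle across degenerate frames
        for t in np.nonzero(~valid)[0]:
            col_vals[t] = col_vals[t - 1]
        ang[:, col] = col_vals
    return ang


def compute_derivatives(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference velocity and acceleration of a (T, k) signal.

    Central differences at interior frames, one-sided at the boundaries;
    acceleration applies the same operator to the velocity.  Units are
    per-frame.
    """
    r = np.asarray(r, dtype=float)
    if r.shape[0] < 3:
        raise KinematicsError(f"at least 3 frames required for derivatives, got {r.shape[0]}")

    def diff(x: np.ndarray) -> np.ndarray:
        d = np.empty_like(x)
        d[1:-1] = (x[2:] - x[:-2]) / 2.0
        d[0] = x[1] - x[0]
        d[-1] = x[-1] - x[-2]
        return d

    v = diff(r)
    return v, diff(v)


def assemble_features(
    record: LiftRecord,
    side: str | None = None,
    conf_threshold: float = 0.3,
) -> FeatureSequence:
    """Convert a LiftRecord into its T x 47 feature sequence.

    Gaps are assumed to be already interpolated (see
    ``pose_io.interpolate_gaps``).  When ``side`` is None the visible side
    is selected automatically.
    """
    track = record.track
    if side is None:
        side = select_side(track, conf_threshold)
    joints = extract_sagittal_joints(track, side)
    r = normalize_positions(joints)
    ang = compute_angles(joints)
    v, a = compute_derivatives(r)
    values = np.hstack([r, ang, v, a])
    return FeatureSequence(values=values, fps=track.fps)


def make_instance(
    record: LiftRecord,
    label: "Optional[LoadCategory]" = None,
    side: str | None = None,
) -> LiftInstance:
    """Assemble features for a record and attach its metadata."""
    feats = assemble_features(record, side=side)
    return LiftInstance(
        features=feats,
        label=label,
        subject_id=record.subject_id,
        task=record.task,
        posture=record.posture,
        load_kg=record.load_kg,
    )


# ---------------------------------------------------------------------------
# feature-space operators


def flip_features(f: FeatureSequence) -> FeatureSequence:
    """Mirror a feature sequence horizontally (negate x columns of r, v, a).

    Unsigned angles are mirror-invariant, so the ang slice is untouched;
    the operation is an involution.
    """
    return FeatureSequence(values=f.values * FLIP_SIGN, fps=f.fps)


def add_gaussian_noise(
    f: FeatureSequence, sigma: float, seed: int | np.random.Generator
) -> FeatureSequence:
    """Add i.i.d. zero-mean Gaussian noise of scale ``sigma`` to every entry."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return FeatureSequence(values=f.values.copy(), fps=f.fps)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return FeatureSequence(values=f.values + rng.normal(0.0, sigma, f.values.shape), fps=f.fps)
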