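"""Seeded simulator of sagittal lifting/lowering keypoint tracks.

The generator emulates the structure of a laboratory lifting study —
subjects x postures (mid-shin, knuckle, shoulder) x loads from a fixed
9-value set x tasks (lift, lower) — while giving explicit control over the
coupling between load and kinematics.  Heavier loads make movements slower
and longer: instance duration is ``T0 * (1 + beta * load / 13.6)`` scaled
by a subject-level tempo effect, and because the wrist travels a fixed
distance along a minimum-jerk path, peak wrist speed drops accordingly.

The body is a 2D sagittal chain (ankle anchored): wrist follows the
minimum-jerk path between the posture's start height and the carry height
(reversed for lowering); the hip crouches as the wrist drops; the knee,
trunk flexion and elbow are solved by circle-circle closure, so every limb
segment keeps a constant length within an instance (before pixel jitter).
Joints are rendered to COCO-17 pixels with the far side drawn as a
low-confidence copy, pixel jitter is added, and a tight per-frame bounding
box is computed.

Everything is reproducible: a single SimConfig seed fixes the dataset
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from . import kinematics
from .pose_io import COCO_INDEX, LiftRecord, N_KEYPOINTS, track_from_arrays

#: the study's load set in kg
STUDY_LOADS_KG = (2.7, 4.1, 5.4, 6.8, 8.2, 9.5, 10.9, 12.2, 13.6)
MAX_LOAD_KG = 13.6

#: segment lengths as fractions of stature (standard anthropometric table)
SEGMENT_FRACTIONS = {
    "ankle_height": 0.039,
    "shank": 0.246,   # ankle to knee
    "thigh": 0.245,   # knee to hip
    "trunk": 0.288,   # hip to shoulder
    "upper_arm": 0.186,
    "forearm": 0.146,
    "head": 0.130,    # shoulder to head (nose) point
}

#: start heights of the three postures, as fractions of stature
POSTURE_HEIGHTS = {"mid-shin": 0.162, "knuckle": 0.44, "shoulder": 0.818}
CARRY_HEIGHT = 0.63  # fraction of stature: hold-at-waist height


class SimulationError(RuntimeError):
    """Raised when a profile/posture combination has no feasible geometry."""


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometry and tempo of one simulated participant."""

    subject_id: str
    stature_m: float
    speed_effect: float  # multiplicative tempo effect, ~1
    px_per_m: float = 420.0

    def __post_init__(self) -> None:
        if not (1.4 <= self.stature_m <= 2.1):
            raise ValueError(f"stature out of bounds: {self.stature_m}")
        if self.speed_effect <= 0:
            raise ValueError("speed_effect must be positive")

    def segment_length(self, name: str) -> float:
        return SEGMENT_FRACTIONS[name] * self.stature_m


@dataclass
class SimConfig:
    """Study structure plus the load -> kinematics coupling."""

    n_subjects: int = 19
    postures: tuple[str, ...] = ("mid-shin", "knuckle", "shoulder")
    loads_kg: tuple[float, ...] = STUDY_LOADS_KG
    tasks: tuple[str, ...] = ("lift", "lower")
    fps: float = 30.0
    base_duration_s: float = 2.2
    load_effect: float = 0.5  # beta: duration multiplier 1 + beta*load/13.6
    keypoint_noise_px: float = 1.0
    visible_side: str = "right"
    subject_speed_sd: float = 0.05   # lognormal sd of the subject tempo effect
    instance_speed_sd: float = 0.03  # lognormal sd of per-instance tempo jitter
    dropout_rate: float = 0.0        # fraction of cells randomly excluded
    px_per_m: float = 420.0
    image_size: tuple[int, int] = (1920, 1080)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.load_effect < 0:
            raise ValueError("load_effect (beta) must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        unknown = set(self.loads_kg) - set(STUDY_LOADS_KG)
        if unknown:
            raise ValueError(f"loads outside the study set: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# geometry helpers


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _circle_circle(p: np.ndarray, r1: float, q: np.ndarray, r2: float,
                   prefer: str) -> np.ndarray:
    """Intersection of circles (p, r1) and (q, r2) in the sagittal plane.

    ``prefer`` picks a branch: "up"/"down" by vertical coordinate,
    "forward"/"backward" by horizontal (x grows toward the lifted object).
    Degenerate (collinear) configurations collapse to the point on the
    line between the centres.
    """
    d = np.linalg.norm(q - p)
    if d < 1e-12:
        raise SimulationError("coincident joint centres")
    if d > r1 + r2 or d < abs(r1 - r2):
        raise SimulationError(f"circles do not intersect (d={d:.3f}, r1={r1:.3f}, r2={r2:.3f})")
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h2 = r1**2 - a**2
    h = np.sqrt(max(h2, 0.0))
    mid = p + a * (q - p) / d
    perp = np.array([-(q - p)[1], (q - p)[0]]) / d
    cand1, cand2 = mid + h * perp, mid - h * perp
    axis = 1 if prefer in ("up", "down") else 0
    bigger = prefer in ("up", "forward")
    if (cand1[axis] >= cand2[axis]) == bigger:
        return cand1
    return cand2


def _solve_chain(profile: SubjectProfile, wrist: np.ndarray) -> dict[str, np.ndarray]:
    """Joint positions (metres, y up, ankle at x=0) for one wrist target."""
    H = profile.stature_m
    seg = profile.segment_length
    ankle = np.array([0.0, SEGMENT_FRACTIONS["ankle_height"] * H])
    arm = seg("upper_arm") + seg("forearm")

    # crouch: the hip drops (and shifts back) as the wrist goes below
    # knuckle height; 2% standing knee flexion keeps the leg solvable
    hip_stand = 0.98 * POSTURE_HEIGHTS_HIP * H
    deficit = max(0.0, 0.44 * H - wrist[1])
    drop = min(0.9 * deficit, 0.30 * H)
    hip = np.array([-0.45 * drop, hip_stand - drop])

    leg = seg("shank") + seg("thigh")
    d_hip = np.linalg.norm(hip - ankle)
    if d_hip >= leg:
        hip = ankle + (hip - ankle) * (leg * (1 - 1e-6) / d_hip)
    knee = _circle_circle(ankle, seg("shank"), hip, seg("thigh"), prefer="forward")

    # trunk flexion by closure: shoulder sits on the trunk circle around the
    # hip and on a circle of radius d (comfortable arm extension) around the
    # wrist
    g = np.linalg.norm(hip - wrist)
    d = float(np.clip(0.75 * arm, abs(g - seg("trunk")) + 1e-4, g + seg("trunk") - 1e-4))
    if not (0.2 * arm <= d <= 0.995 * arm):
        raise SimulationError(
            f"unreachable posture geometry: wrist at {wrist}, hip at {hip}"
        )
    shoulder = _circle_circle(hip, seg("trunk"), wrist, d, prefer="up")
    elbow = _circle_circle(shoulder, seg("upper_arm"), wrist, seg("forearm"), prefer="down")

    # head along the trunk direction, tilted slightly forward
    u = (shoulder - hip) / np.linalg.norm(shoulder - hip)
    tilt = 0.15
    rot = np.array([[np.cos(tilt), np.sin(tilt)], [-np.sin(tilt), np.cos(tilt)]])
    head = shoulder + seg("head") * (rot @ u)
    return {
        "ankle": ankle, "knee": knee, "hip": hip, "shoulder": shoulder,
        "elbow": elbow, "wrist": wrist, "head": head,
    }


POSTURE_HEIGHTS_HIP = 0.530  # standing hip height fraction of stature


# ---------------------------------------------------------------------------
# simulation


def _render_coco(joints_seq: list[dict[str, np.ndarray]], profile: SubjectProfile,
                 config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Project the chain to COCO-17 pixel keypoints with confidences."""
    T = len(joints_seq)
    ppm = profile.px_per_m
    cx = config.image_size[0] * 0.5
    ground_y = config.image_size[1] * 0.92
    sign = 1.0 if config.visible_side == "right" else -1.0

    kpts = np.zeros((T, N_KEYPOINTS, 3))
    near = config.visible_side
    far = "left" if near == "right" else "right"
    for t, joints in enumerate(joints_seq):
        def to_px(p):
            return np.array([cx + sign * p[0] * ppm, ground_y - p[1] * ppm])

        head_px = to_px(joints["head"])
        kpts[t, COCO_INDEX["nose"], :2] = head_px
        kpts[t, COCO_INDEX["nose"], 2] = 0.9
        for eye_side, conf in ((near, 0.8), (far, 0.2)):
            s = 1.0 if eye_side == near else 0.6
            kpts[t, COCO_INDEX[f"{eye_side}_eye"], :2] = head_px + [sign * 6 * s, -8]
            kpts[t, COCO_INDEX[f"{eye_side}_eye"], 2] = conf
            kpts[t, COCO_INDEX[f"{eye_side}_ear"], :2] = head_px + [-sign * 10 * s, 0]
            kpts[t, COCO_INDEX[f"{eye_side}_ear"], 2] = conf
        for name in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle"):
            p = to_px(joints[name])
            kpts[t, COCO_INDEX[f"{near}_{name}"], :2] = p
            kpts[t, COCO_INDEX[f"{near}_{name}"], 2] = 0.92
            # far side occluded: rendered as a copy at low confidence
            kpts[t, COCO_INDEX[f"{far}_{name}"], :2] = p
            kpts[t, COCO_INDEX[f"{far}_{name}"], 2] = 0.2
    if config.keypoint_noise_px > 0:
        kpts[:, :, :2] += rng.normal(0.0, config.keypoint_noise_px, (T, N_KEYPOINTS, 2))
    return kpts


def simulate_lift_instance(
    profile: SubjectProfile,
    posture: str,
    load_kg: float,
    task: str,
    config: SimConfig,
    seed: int,
) -> LiftRecord:
    """Simulate one lifting or lowering instance as a validated LiftRecord.

    Duration is ``T0 * (1 + beta * load / max_load) * speed_effect`` (times
    a small per-instance tempo jitter); lowering reverses the lift's wrist
    height profile.  The same seed reproduces the record exactly.
    """
    if posture not in POSTURE_HEIGHTS:
        raise ValueError(f"unknown posture {posture!r}")
    rng = np.random.default_rng(seed)
    H = profile.stature_m
    jitter = float(np.exp(rng.normal(0.0, config.instance_speed_sd))) if config.instance_speed_sd > 0 else 1.0
    duration = (config.base_duration_s
                * (1.0 + config.load_effect * load_kg / MAX_LOAD_KG)
                * profile.speed_effect * jitter)
    T = max(int(round(duration * config.fps)), 3)

    start = np.array([0.32 * H / 1.7, POSTURE_HEIGHTS[posture] * H])
    end = np.array([0.26 * H / 1.7, CARRY_HEIGHT * H])
    if task == "lower":
        start, end = end, start
    elif task != "lift":
        raise ValueError(f"unknown task {task!r}")

    tau = np.arange(T) / (T - 1)
    s = _min_jerk(tau)
    wrists = start[None, :] + s[:, None] * (end - start)[None, :]
    joints_seq = [_solve_chain(profile, w) for w in wrists]
    kpts = _render_coco(joints_seq, profile, config, rng)
    track = track_from_arrays(
        kpts, None, fps=config.fps,
        video_id=f"{profile.subject_id}_{posture}_{load_kg}_{task}",
    )
    return LiftRecord(
        track=track,
        subject_id=profile.subject_id,
        task=task,
        posture=posture,
        load_kg=load_kg,
        onset_frame=0,
        offset_frame=T - 1,
    )


def make_profiles(config: SimConfig) -> list[SubjectProfile]:
    """Draw the subject panel (stature, tempo) from the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 91]))
    profiles = []
    for i in range(config.n_subjects):
        stature = float(rng.normal(1.7, 0.1))
        while not (1.4 <= stature <= 2.1):  # truncated normal by resampling
            stature = float(rng.normal(1.7, 0.1))
        speed = float(np.exp(rng.normal(0.0, config.subject_speed_sd)))
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i:02d}",
                stature_m=stature,
                speed_effect=speed,
                px_per_m=config.px_per_m,
            )
        )
    return profiles


def generate_dataset(config: SimConfig) -> list[LiftRecord]:
    """Full factorial subjects x postures x loads x tasks, seeded globally.

    With 19 subjects, 3 postures, 9 loads and both tasks this yields 1026
    records; a positive ``dropout_rate`` randomly excludes cells to mimic
    real-study exclusions.
    """
    profiles = make_profiles(config)
    drop_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 92]))
    seed_seq = np.random.SeedSequence([config.seed, 93])
    records = []
    combos = [
        (profile, posture, load, task)
        for profile in profiles
        for posture in config.postures
        for load in config.loads_kg
        for task in config.tasks
    ]
    child_seeds = seed_seq.generate_state(len(combos)) >> 1  # keep below 2**31
    for (profile, posture, load, task), child in zip(combos, child_seeds):
        if config.dropout_rate > 0 and drop_rng.random() < config.dropout_rate:
            continue
        records.append(
            simulate_lift_instance(profile, posture, load, task, config, int(child))
        )
    return records


# ---------------------------------------------------------------------------
# signal diagnostics


@dataclass
class SignalSummary:
    """Per-category wrist/hip displacement curves and peak-speed stats."""

    categories: list[str]
    n_per_category: dict[str, int]
    wrist_curves: dict[str, np.ndarray]  # mean normalised |displacement|, resampled
    hip_curves: dict[str, np.ndarray]
    peak_speeds: dict[str, np.ndarray]  # per-instance normalised peak wrist speed
    light_vs_heavy_p: float
    monotone_decreasing: bool


def _category_of(load: float) -> str:
    from .training_eval import categorize_load

    return categorize_load(load).value


def kinematic_signal_check(dataset: Sequence[LiftRecord], n_points: int = 50) -> SignalSummary:
    """Summarise the load -> kinematics coupling in a generated dataset.

    Computes bounding-box-normalised wrist and hip displacement curves
    (resampled to a common length) and per-instance peak wrist speeds per
    load category, plus a Welch test comparing light vs heavy peak speeds.
    ``monotone_decreasing`` records whether mean peak speed decreases from
    light through medium to heavy — the expected signature when beta > 0.
    """
    curves_w: dict[str, list] = {}
    curves_h: dict[str, list] = {}
    speeds: dict[str, list] = {}
    grid = np.linspace(0.0, 1.0, n_points)
    for rec in dataset:
        cat = _category_of(rec.load_kg)
        kpts = rec.track.keypoint_array()
        side = "right" if kpts[:, COCO_INDEX["right_wrist"], 2].mean() >= kpts[:, COCO_INDEX["left_wrist"], 2].mean() else "left"
        h_max = rec.track.bbox_array()[:, 3].max()
        wrist = kpts[:, COCO_INDEX[f"{side}_wrist"], :2] / h_max
        hip = kpts[:, COCO_INDEX[f"{side}_hip"], :2] / h_max
        T = wrist.shape[0]
        tau = np.arange(T) / (T - 1)
        disp_w = np.linalg.norm(wrist - wrist[0], axis=1)
        disp_h = np.linalg.norm(hip - hip[0], axis=1)
        curves_w.setdefault(cat, []).append(np.interp(grid, tau, disp_w))
        curves_h.setdefault(cat, []).append(np.interp(grid, tau, disp_h))
        speed = np.linalg.norm(np.diff(wrist, axis=0), axis=1) * rec.track.fps
        speeds.setdefault(cat, []).append(speed.max())
    cats = [c for c in ("light", "medium", "heavy") if c in speeds]
    peak = {c: np.array(speeds[c]) for c in cats}
    means = [peak[c].mean() for c in cats]
    mono = all(a > b for a, b in zip(means, means[1:]))
    if "light" in peak and "heavy" in peak:
        p = float(stats.ttest_ind(peak["light"], peak["heavy"], equal_var=False).pvalue)
    else:
        p = float("nan")
    return SignalSummary(
        categories=cats,
        n_per_category={c: len(peak[c]) for c in cats},
        wrist_curves={c: np.mean(curves_w[c], axis=0) for c in cats},
        hip_curves={c: np.mean(curves_h[c], axis=0) for c in cats},
        peak_speeds=peak,
        light_vs_heavy_p=p,
        monotone_decreasing=mono,
    )


def dataset_to_instances(records: Sequence[LiftRecord]) -> list:
    """Extract features and labels for every record (the full pipeline)."""
    from .training_eval import categorize_load

    instances = []
    for rec in records:
        instances.append(
            kinematics.make_instance(rec, label=categorize_load(rec.load_kg))
        )
    return instances
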