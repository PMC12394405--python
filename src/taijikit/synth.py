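"""Seeded synthetic skeleton data: motion, camera views, injected errors.

Motion is defined in joint-angle space on a fixed 32-joint rest skeleton
and realized by forward kinematics, so bone lengths are conserved exactly
— synthetic skeletons must not be rubber.  A movement unit animates a set
of joints with sums of up to three sinusoids plus a smooth drift, all
scaled by a sin^2 envelope so every unit starts and ends at the rest pose
with zero velocity; stillness gaps between units hold the rest pose, and
ground-truth segment boundaries sit exactly at gap midpoints.

Camera views are exact pinhole projections of the generated joints with
optional Gaussian pixel noise (confidence = exp(-noise magnitude)) and
visibility dropout.  Error injection applies category-specific geometric
perturbations (torso lean, knee translation past the toe, pelvis weight
shift, shoulder raise, hip yaw offset, elbow over-extension) confined to a
frame interval with 5-frame cosine ramps.

All randomness flows through one seeded generator recorded in the output
metadata; every generator is bit-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from taijikit.error_metrics import ERROR_CATEGORIES
from taijikit.layout import JOINT_NAMES_32, PARENTS_32, skeleton_edges
from taijikit.multiview import CameraModel, Observation2D
from taijikit.segmentation import Segment, Template
from taijikit.skeleton import SkeletonSequence

__all__ = [
    "MotionSpec",
    "UnitSpec",
    "ErrorInjection",
    "TrainingSet",
    "rest_offsets",
    "random_unit_spec",
    "generate_motion",
    "unit_template",
    "camera_ring",
    "render_views",
    "inject_error",
    "make_training_set",
]

J32 = {n: i for i, n in enumerate(JOINT_NAMES_32)}

# bone offsets from parent in the rest pose (meters); standing, z up,
# left = +x, forward = +y; slight elbow/knee bends keep local frames
# well-defined everywhere
_REST_OFFSETS = {
    "pelvis": (0.0, 0.0, 1.00),
    "spine_01": (0.0, 0.0, 0.10),
    "spine_02": (0.0, 0.0, 0.10),
    "spine_03": (0.0, 0.0, 0.10),
    "chest": (0.0, 0.0, 0.10),
    "neck": (0.0, 0.0, 0.12),
    "head": (0.0, 0.01, 0.10),
    "head_top": (0.0, 0.0, 0.12),
    "clavicle_l": (0.08, 0.0, 0.05),
    "shoulder_l": (0.12, 0.0, 0.0),
    "elbow_l": (0.10, 0.05, -0.24),
    "wrist_l": (0.06, 0.10, -0.20),
    "hand_l": (0.02, 0.04, -0.05),
    "hand_tip_l": (0.01, 0.03, -0.03),
    "thumb_l": (0.03, 0.02, -0.01),
    "clavicle_r": (-0.08, 0.0, 0.05),
    "shoulder_r": (-0.12, 0.0, 0.0),
    "elbow_r": (-0.10, 0.05, -0.24),
    "wrist_r": (-0.06, 0.10, -0.20),
    "hand_r": (-0.02, 0.04, -0.05),
    "hand_tip_r": (-0.01, 0.03, -0.03),
    "thumb_r": (-0.03, 0.02, -0.01),
    "hip_l": (0.10, 0.0, -0.02),
    "knee_l": (0.01, 0.02, -0.42),
    "ankle_l": (0.0, -0.04, -0.44),
    "heel_l": (0.0, -0.06, -0.10),
    "foot_l": (0.0, 0.14, -0.10),
    "hip_r": (-0.10, 0.0, -0.02),
    "knee_r": (-0.01, 0.02, -0.42),
    "ankle_r": (0.0, -0.04, -0.44),
    "heel_r": (0.0, -0.06, -0.10),
    "foot_r": (-0.0, 0.14, -0.10),
}

# joints a movement unit may animate, with the local rotation axis and a
# plausible amplitude ceiling (radians)
_ANIMATABLE = {
    "shoulder_l": (("x", 0.7), ("y", 0.5)),
    "shoulder_r": (("x", 0.7), ("y", 0.5)),
    "elbow_l": (("z", 0.6),),
    "elbow_r": (("z", 0.6),),
    "spine_01": (("z", 0.25), ("x", 0.12)),
    "pelvis": (("z", 0.35),),
    "hip_l": (("x", 0.2),),
    "hip_r": (("x", 0.2),),
    "knee_l": (("x", 0.25),),
    "knee_r": (("x", 0.25),),
}


def rest_offsets() -> np.ndarray:
    """(32, 3) bone offsets from parent (root offset = world position)."""
    return np.array([_REST_OFFSETS[n] for n in JOINT_NAMES_32])


def _forward_kinematics(angles: dict[int, np.ndarray]) -> np.ndarray:
    """Positions (T, 32, 3) from per-joint rotation-vector tracks (T, 3)."""
    offsets = rest_offsets()
    some = next(iter(angles.values()))
    T = some.shape[0]
    pos = np.zeros((T, 32, 3))
    rot_global = [None] * 32
    eye = np.broadcast_to(np.eye(3), (T, 3, 3))
    for j in range(32):
        p = PARENTS_32[j]
        local = (
            Rotation.from_rotvec(angles[j]).as_matrix() if j in angles else eye
        )
        if p < 0:
            rot_global[j] = local
            pos[:, j] = offsets[j]
        else:
            rot_global[j] = rot_global[p] @ local
            pos[:, j] = pos[:, p] + np.einsum(
                "tij,j->ti", rot_global[p], offsets[j]
            )
    return pos


_AXIS = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
         "z": np.array([0, 0, 1.0])}


@dataclass(frozen=True)
class UnitSpec:
    """One parametric movement unit.

    ``channels`` maps joint name -> (axis letter, harmonics, drift) where
    harmonics is a tuple of (amplitude_rad, cycles, phase) triples (at most
    three) and drift a tuple of spline control values (radians).
    """

    duration: int
    channels: dict[str, tuple]
    unit_id: str = "unit"

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("unit duration must be >= 1")


@dataclass(frozen=True)
class MotionSpec:
    movement_units: tuple[UnitSpec, ...]
    stillness_gap: int = 15
    noise_sd: float = 0.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.stillness_gap < 0:
            raise ValueError("stillness_gap must be >= 0")


def random_unit_spec(
    rng: np.random.Generator, duration: int, n_joints: int = 6,
    unit_id: str = "unit",
) -> UnitSpec:
    """Draw a random movement unit animating ``n_joints`` joints."""
    names = list(_ANIMATABLE)
    chosen = rng.choice(len(names), size=min(n_joints, len(names)), replace=False)
    channels: dict[str, tuple] = {}
    for ci in chosen:
        name = names[ci]
        axis, ceil = _ANIMATABLE[name][rng.integers(len(_ANIMATABLE[name]))]
        n_h = int(rng.integers(1, 4))  # up to three sinusoids
        harmonics = tuple(
            (float(rng.uniform(0.3, 1.0) * ceil / n_h),
             int(rng.integers(1, 4)),
             float(rng.uniform(0, 2 * np.pi)))
            for _ in range(n_h)
        )
        drift = tuple(float(x) for x in rng.uniform(-0.15, 0.15, size=4) * ceil)
        channels[name] = (axis, harmonics, drift)
    return UnitSpec(duration=duration, channels=channels, unit_id=unit_id)


def _unit_angles(spec: UnitSpec) -> dict[int, np.ndarray]:
    """Rotation-vector tracks (T, 3) per animated joint for one unit."""
    T = spec.duration
    t = np.arange(T) / max(T - 1, 1)
    envelope = np.sin(np.pi * t) ** 2  # rest pose and zero velocity at ends
    out: dict[int, np.ndarray] = {}
    for name, (axis, harmonics, drift) in spec.channels.items():
        angle = np.zeros(T)
        for amp, cycles, phase in harmonics:
            angle += amp * np.sin(2 * np.pi * cycles * t + phase)
        if drift:
            # smooth drift through control points (cubic polyfit)
            ctrl_t = np.linspace(0, 1, len(drift))
            coeffs = np.polyfit(ctrl_t, drift, deg=min(3, len(drift) - 1))
            angle += np.polyval(coeffs, t)
        angle *= envelope
        out[J32[name]] = angle[:, None] * _AXIS[axis][None, :]
    return out


def generate_motion(
    spec: MotionSpec,
) -> tuple[SkeletonSequence, list[Segment]]:
    """Generate a continuous sequence with known segment boundaries.

    Units are separated by ``stillness_gap`` frames of held rest pose;
    ground-truth boundaries sit exactly at the gap midpoints, and the
    returned segments cover [0, T) contiguously.
    """
    rng = np.random.default_rng(spec.seed)
    blocks: list[np.ndarray] = []
    unit_bounds: list[tuple[int, int, str]] = []
    cursor = 0
    for u_i, unit in enumerate(spec.movement_units):
        angle_tracks = _unit_angles(unit) or {0: np.zeros((unit.duration, 3))}
        pos = _forward_kinematics(angle_tracks)
        blocks.append(pos)
        unit_bounds.append((cursor, cursor + unit.duration, unit.unit_id))
        cursor += unit.duration
        if u_i < len(spec.movement_units) - 1 and spec.stillness_gap > 0:
            rest = np.repeat(pos[-1:][:, :, :] * 0, spec.stillness_gap, axis=0)
            rest += _forward_kinematics({0: np.zeros((1, 3))})[0]
            blocks.append(rest)
            cursor += spec.stillness_gap
    positions = np.concatenate(blocks, axis=0)
    if spec.noise_sd > 0:
        positions = positions + rng.normal(0.0, spec.noise_sd, positions.shape)
    T = positions.shape[0]
    seq = SkeletonSequence(
        positions=positions,
        confidence=np.ones((T, 32)),
        fps=spec.fps,
        joint_names=JOINT_NAMES_32,
        edges=tuple(skeleton_edges()),
        meta={"seed": spec.seed, "generator": "generate_motion"},
    )
    # ground-truth boundaries at stillness-gap midpoints
    segments: list[Segment] = []
    prev = 0
    for k, (s, e, uid) in enumerate(unit_bounds):
        if k < len(unit_bounds) - 1:
            boundary = e + spec.stillness_gap // 2
        else:
            boundary = T
        segments.append(
            Segment(start=prev, end=boundary, label=uid, dtw_distance=0.0,
                    valid=True)
        )
        prev = boundary
    return seq, segments


def unit_template(unit: UnitSpec, fps: float = 30.0) -> Template:
    """Render a movement unit alone as a labeling template."""
    angle_tracks = _unit_angles(unit) or {0: np.zeros((unit.duration, 3))}
    pos = _forward_kinematics(angle_tracks)
    seq = SkeletonSequence(
        positions=pos,
        confidence=np.ones((pos.shape[0], 32)),
        fps=fps,
        joint_names=JOINT_NAMES_32,
        edges=tuple(skeleton_edges()),
    )
    return Template(template_id=unit.unit_id, reference=seq)


# ---------------------------------------------------------------------------
# camera synthesis


def _look_at(center: np.ndarray, target: np.ndarray) -> np.ndarray:
    """World->camera rotation with +z toward the target, y pointing down."""
    fwd = target - center
    fwd = fwd / np.linalg.norm(fwd)
    up_world = np.array([0.0, 0.0, 1.0])
    right = np.cross(fwd, up_world)
    if np.linalg.norm(right) < 1e-9:
        right = np.array([1.0, 0.0, 0.0])
    right = right / np.linalg.norm(right)
    down = np.cross(fwd, right)
    return np.stack([right, down, fwd], axis=0)


def camera_ring(
    n_cameras: int = 8,
    radius: float = 3.5,
    heights: tuple[float, float] = (1.5, 2.5),
    target: tuple[float, float, float] = (0.0, 0.0, 1.0),
    focal_px: float = 1000.0,
    principal: tuple[float, float] = (960.0, 540.0),
) -> list[CameraModel]:
    """Circular capture rig: cameras at equal angular intervals around the
    performer, alternating between two mounting heights."""
    tgt = np.asarray(target, float)
    cams = []
    for i in range(n_cameras):
        ang = 2 * np.pi * i / n_cameras
        h = heights[i % 2]
        c = np.array([radius * np.cos(ang), radius * np.sin(ang), h])
        K = np.array(
            [[focal_px, 0, principal[0]], [0, focal_px, principal[1]], [0, 0, 1]]
        )
        cams.append(CameraModel(K=K, R=_look_at(c, tgt), C=c, cam_id=f"cam{i}"))
    return cams


def render_views(
    seq: SkeletonSequence,
    cameras: list[CameraModel],
    pixel_noise_sd: float = 0.0,
    visibility_dropout: float = 0.0,
    seed: int = 0,
) -> list[dict[int, list[Observation2D]]]:
    """Project a sequence into per-view 2D observation streams.

    Exact pinhole projection plus Gaussian pixel noise; the observation
    confidence is the proxy exp(-|noise| / 1 px).  ``visibility_dropout``
    marks joints unobserved in a view at random.  Joints behind any camera
    are a generator-placement bug and raise.
    """
    rng = np.random.default_rng(seed)
    frames_obs: list[dict[int, list[Observation2D]]] = []
    for t in range(seq.n_frames):
        obs_t: dict[int, list[Observation2D]] = {}
        for j in range(seq.n_joints):
            obs_j = []
            for cam in cameras:
                if visibility_dropout > 0 and rng.random() < visibility_dropout:
                    continue
                xc = cam.R @ (seq.positions[t, j] - cam.C)
                if xc[2] <= 0:
                    raise RuntimeError(
                        f"joint {j} behind camera {cam.cam_id} at frame {t}; "
                        "regenerate placement"
                    )
                uvw = cam.K @ xc
                px = uvw[:2] / uvw[2]
                if pixel_noise_sd > 0:
                    noise = rng.normal(0.0, pixel_noise_sd, 2)
                    px = px + noise
                    conf = float(np.exp(-np.linalg.norm(noise)))
                else:
                    conf = 1.0
                obs_j.append(
                    Observation2D(view_id=cam.cam_id, pixel=px, weight=conf)
                )
            obs_t[j] = obs_j
        frames_obs.append(obs_t)
    return frames_obs


# ---------------------------------------------------------------------------
# error injection


@dataclass(frozen=True)
class ErrorInjection:
    """A deterministic category-specific perturbation of a clean sequence."""

    category: str
    magnitude: float          # degrees (angular) or meters (positional)
    frames: tuple[int, int] | None = None
    side: str = "l"
    ramp_frames: int = 5

    def __post_init__(self) -> None:
        if self.category not in ERROR_CATEGORIES:
            raise ValueError(f"unknown error category {self.category!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


def _ramp(T: int, frames: tuple[int, int], n: int) -> np.ndarray:
    """Cosine on/off ramp over ``n`` frames inside the interval, 0 outside."""
    s, e = frames
    w = np.zeros(T)
    w[s:e] = 1.0
    n = min(n, max((e - s) // 2, 1))
    up = 0.5 * (1 - np.cos(np.pi * (np.arange(n) + 1) / n))
    w[s:s + n] = up
    w[e - n:e] = up[::-1]
    return w


def _descendants(root_names: list[str]) -> list[int]:
    roots = {J32[n] for n in root_names}
    out = set(roots)
    changed = True
    while changed:
        changed = False
        for c, p in enumerate(PARENTS_32):
            if p in out and c not in out:
                out.add(c)
                changed = True
    return sorted(out)


def _rotate_about(
    pos: np.ndarray, idxs: list[int], pivot: np.ndarray, axis: np.ndarray,
    angles: np.ndarray,
) -> None:
    """In-place rotation of selected joints about a per-frame pivot/axis."""
    for t in np.nonzero(angles)[0]:
        rot = Rotation.from_rotvec(axis[t] * angles[t]).as_matrix()
        pos[t, idxs] = (pos[t, idxs] - pivot[t]) @ rot.T + pivot[t]


def inject_error(
    seq: SkeletonSequence, injection: ErrorInjection
) -> tuple[SkeletonSequence, dict]:
    """Apply one category-specific perturbation; returns (sequence, label).

    magnitude 0 returns the sequence unchanged.  The perturbation is
    confined to ``injection.frames`` with cosine ramps; the label dict
    records the category, magnitude and interval for ground truth.
    """
    T = seq.n_frames
    frames = injection.frames or (0, T)
    pos = seq.positions.copy()
    w = _ramp(T, frames, injection.ramp_frames)
    cat = injection.category
    side = injection.side
    if cat == "spine_alignment":
        # forward lean: rotate the torso chain (and arms) about the pelvis
        idxs = _descendants(["spine_01"])
        pivot = seq.positions[:, J32["pelvis"]]
        axis = np.tile(np.array([1.0, 0, 0]), (T, 1))  # lean about the l-r axis
        _rotate_about(pos, idxs, pivot, axis, np.deg2rad(injection.magnitude) * w)
    elif cat == "knee_position":
        knee = J32[f"knee_{side}"]
        ankle = seq.positions[:, J32[f"ankle_{side}"], :2]
        toe = seq.positions[:, J32[f"foot_{side}"], :2]
        axis = toe - ankle
        axis = axis / np.maximum(np.linalg.norm(axis, axis=1, keepdims=True), 1e-9)
        shift = np.zeros((T, 3))
        shift[:, :2] = axis * (injection.magnitude * w)[:, None]
        pos[:, knee] += shift
    elif cat == "weight_distribution":
        # shift everything but the planted feet toward one side
        planted = {
            J32[n] for n in
            ("ankle_l", "heel_l", "foot_l", "ankle_r", "heel_r", "foot_r")
        }
        idxs = [j for j in range(32) if j not in planted]
        sign = 1.0 if side == "l" else -1.0
        pos[:, idxs, 0] += sign * injection.magnitude * w[:, None]
    elif cat == "shoulder_tension":
        idxs = sorted(
            set(_descendants(["clavicle_l", "clavicle_r"]))
        )
        pos[:, idxs, 2] += injection.magnitude * w[:, None]
    elif cat == "hip_rotation":
        idxs = _descendants(["hip_l", "hip_r"])
        pivot = seq.positions[:, J32["pelvis"]]
        axis = np.tile(np.array([0.0, 0, 1.0]), (T, 1))
        _rotate_about(pos, idxs, pivot, axis, np.deg2rad(injection.magnitude) * w)
    elif cat == "arm_extension":
        # bend the elbow away from the reference angle about the flexion
        # axis; the flexing direction keeps the deviation linear in the
        # magnitude (opening saturates at a straight arm)
        sh = seq.positions[:, J32[f"shoulder_{side}"]]
        el = seq.positions[:, J32[f"elbow_{side}"]]
        wr = seq.positions[:, J32[f"wrist_{side}"]]
        u = sh - el
        v = wr - el
        n = np.cross(v, u)  # rotating v toward u closes the elbow
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / np.maximum(norm, 1e-9)
        idxs = _descendants([f"wrist_{side}"])
        _rotate_about(pos, idxs, el, n, np.deg2rad(injection.magnitude) * w)
    else:  # pragma: no cover - guarded by ErrorInjection
        raise ValueError(f"unknown error category {cat!r}")
    label = {
        "category": cat,
        "magnitude": injection.magnitude,
        "frames": frames,
        "side": side,
    }
    return seq.with_positions(pos), label


# ---------------------------------------------------------------------------
# labeled training sets


# class-conditional error profiles anchored to the quality rubric: worse
# levels show larger deviations, *more* co-occurring error categories and
# rougher execution (uneven rhythm -> motion jitter).  Magnitudes in
# degrees for angular categories; meters = 0.006 m per degree-band unit
# for positional ones.
_CLASS_BANDS_DEG = {
    0: (0.0, 0.0),     # Excellent: clean
    1: (6.0, 9.0),     # Good
    2: (11.0, 14.0),   # Fair
    3: (16.0, 25.0),   # NeedsImprovement
}
_CLASS_N_CATEGORIES = {0: 0, 1: 1, 2: 2, 3: 3}
_CLASS_JITTER_SD = {0: 0.0, 1: 0.002, 2: 0.004, 3: 0.007}
_METERS_PER_DEG = 0.006
_ANGULAR = {"spine_alignment", "arm_extension", "hip_rotation"}
_STAGES = ("posture", "transition", "sequence")


@dataclass
class TrainingSet:
    items: np.ndarray            # (N, 32, 3, 150) normalized coordinates
    labels: np.ndarray           # (N,) int class 0..3
    stages: list[str]            # curriculum stage per item
    sequences: list[SkeletonSequence] = field(repr=False, default_factory=list)
    references: list[SkeletonSequence] = field(repr=False, default_factory=list)
    injections: list[list[dict]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def hash(self) -> str:
        import hashlib

        h = hashlib.sha256(self.items.tobytes())
        h.update(self.labels.tobytes())
        return h.hexdigest()


def _normalize_item(positions: np.ndarray, scale_m: float = 1.0) -> np.ndarray:
    """(T, 32, 3) -> (32, 3, T), pelvis-centered, coordinates in [-1, 1].

    The scale is a fixed body-extent constant (1 m), not a per-item
    maximum: absolute deviation magnitudes carry the quality signal and
    must survive normalization.
    """
    root = positions[:, :1, :].mean(axis=0, keepdims=True)
    return ((positions - root) / scale_m).transpose(1, 2, 0)


# fixed seed defining the canonical forms themselves: every dataset uses
# the same standard movements, as practitioners of one school would
_CANONICAL_SEED = 7


def _rescale_unit(unit: UnitSpec, factor: float, duration: int | None = None,
                  unit_id: str | None = None) -> UnitSpec:
    scaled = {}
    for name, (axis, harm, drift) in unit.channels.items():
        harm2 = tuple((a * factor, c, p) for a, c, p in harm)
        scaled[name] = (axis, harm2, tuple(d * factor for d in drift))
    return UnitSpec(duration or unit.duration, scaled, unit_id or unit.unit_id)


def canonical_forms(frames: int = 150) -> dict[str, tuple[UnitSpec, ...]]:
    """The standard movement per curriculum stage, shared by all subjects.

    A *posture* is a near-static hold, a *transition* one full movement
    unit, a *sequence* two units separated by a stillness gap.
    """
    r = np.random.default_rng(_CANONICAL_SEED)
    hold = _rescale_unit(
        random_unit_spec(r, frames, n_joints=2, unit_id="hold"), 0.1
    )
    move = random_unit_spec(r, frames, unit_id="move")
    gap = 20
    d1 = (frames - gap) // 2
    u1 = random_unit_spec(r, d1, unit_id="u1")
    u2 = random_unit_spec(r, frames - gap - d1, unit_id="u2")
    return {"posture": (hold,), "transition": (move,), "sequence": (u1, u2)}


def _subject_variation(unit: UnitSpec, rng: np.random.Generator,
                       amp_jitter: float = 0.05,
                       phase_jitter: float = 0.05) -> UnitSpec:
    """Small per-subject deviation from the canonical form."""
    varied = {}
    for name, (axis, harm, drift) in unit.channels.items():
        harm2 = tuple(
            (a * float(rng.uniform(1 - amp_jitter, 1 + amp_jitter)),
             c,
             p + float(rng.uniform(-phase_jitter, phase_jitter)))
            for a, c, p in harm
        )
        varied[name] = (axis, harm2, drift)
    return UnitSpec(unit.duration, varied, unit.unit_id)


def _stage_motion(stage: str, rng: np.random.Generator, frames: int,
                  fps: float) -> tuple[SkeletonSequence, MotionSpec]:
    seed = int(rng.integers(2**31 - 1))
    canonical = canonical_forms(frames)[stage]
    units = tuple(_subject_variation(u, rng) for u in canonical)
    gap = 20 if stage == "sequence" else 0
    spec = MotionSpec(units, stillness_gap=gap, fps=fps, seed=seed)
    seq, _ = generate_motion(spec)
    return seq, spec


def make_training_set(
    n_per_class: int = 10,
    seed: int = 0,
    frames: int = 150,
    fps: float = 30.0,
    sensor_noise_sd: float = 0.002,
) -> TrainingSet:
    """Balanced, shuffled, seeded 4-class dataset of 150-frame items.

    Class 0 (Excellent) items are clean replays of their reference;
    classes 1-3 carry an escalating number of injected error categories
    (1/2/3) with magnitudes drawn from the class's rubric-anchored band,
    plus class-scaled execution jitter.  Items are tagged with curriculum
    stages (posture / transition / sequence, cycled).
    """
    rng = np.random.default_rng(seed)
    items, labels, stages = [], [], []
    seqs, refs, inj_lists = [], [], []
    for cls in range(4):
        for i in range(n_per_class):
            stage = _STAGES[(cls * n_per_class + i) % 3]
            ref, _ = _stage_motion(stage, rng, frames, fps)
            seq = ref
            applied: list[dict] = []
            lo, hi = _CLASS_BANDS_DEG[cls]
            n_cat = _CLASS_N_CATEGORIES[cls]
            if n_cat > 0:
                cats = rng.choice(len(ERROR_CATEGORIES), size=n_cat,
                                  replace=False)
                for c in cats:
                    cat = ERROR_CATEGORIES[c]
                    mag_deg = float(rng.uniform(lo, hi))
                    if cat in _ANGULAR:
                        mag = mag_deg
                    elif cat == "weight_distribution":
                        mag = mag_deg * _METERS_PER_DEG * 2.0  # pelvis shift
                    else:
                        mag = mag_deg * _METERS_PER_DEG
                    side = "l" if rng.random() < 0.5 else "r"
                    seq, label = inject_error(
                        seq, ErrorInjection(category=cat, magnitude=mag,
                                            side=side)
                    )
                    applied.append(label)
            noisy = seq.positions
            total_sd = float(
                np.hypot(sensor_noise_sd, _CLASS_JITTER_SD[cls])
            )
            if total_sd > 0:
                noisy = noisy + rng.normal(0.0, total_sd, noisy.shape)
            items.append(_normalize_item(noisy))
            labels.append(cls)
            stages.append(stage)
            seqs.append(seq.with_positions(noisy))
            refs.append(ref)
            inj_lists.append(applied)
    order = rng.permutation(len(items))
    return TrainingSet(
        items=np.stack(items)[order],
        labels=np.array(labels)[order],
        stages=[stages[i] for i in order],
        sequences=[seqs[i] for i in order],
        references=[refs[i] for i in order],
        injections=[inj_lists[i] for i in order],
        meta={"seed": seed, "n_per_class": n_per_class, "frames": frames},
    )
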