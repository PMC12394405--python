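"""Quantitative movement-error detection and severity grading.

Deviations between a performed and a reference sequence are measured with
rotation-invariant local-frame joint angles (quaternion geodesic angle
dtheta = 2 arccos(|q_ref . q_perf|)), trajectory error

    E_traj = (1/T) sum_t sqrt(||p - p_ref||^2 + alpha ||v - v_ref||^2),

an inter-segment coordination index (mean over paired signals of the
maximal normalized cross-correlation across lags), and a stability score
combining static center-of-mass sway with the excursion of the dynamic
center of mass beyond the base of support.

A rule engine maps derived per-frame deviation signals onto six error
categories (weight distribution, spine alignment, arm extension, knee
position, hip rotation, shoulder tension).  A rule fires only when its
signal exceeds the category threshold over a sustained window (default
0.5 s) — momentary spikes are not errors.  Severity follows the
+-5/10/15 degree rubric bands; non-angular categories are graded on the
equivalent multiple of their own threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from taijikit.layout import parents as layout_parents
from taijikit.skeleton import (
    SkeletonSequence,
    SupportPolygon,
    UnitQuaternion,
    center_of_mass,
    point_to_polygon_distance,
    quaternion_angle,
)

__all__ = [
    "TrajectoryErrorConfig",
    "StabilityConfig",
    "ErrorReport",
    "ERROR_CATEGORIES",
    "joint_angle_deviations",
    "trajectory_error",
    "coordination_index",
    "stability_metric",
    "classify_errors",
    "severity_grade",
    "CategoryThresholds",
]

ERROR_CATEGORIES = (
    "weight_distribution",
    "spine_alignment",
    "arm_extension",
    "knee_position",
    "hip_rotation",
    "shoulder_tension",
)

SEVERITY_LEVELS = ("within_standard", "minor", "moderate", "severe")


@dataclass(frozen=True)
class TrajectoryErrorConfig:
    alpha_vel: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_vel < 0:
            raise ValueError("alpha_vel must be >= 0")


@dataclass(frozen=True)
class StabilityConfig:
    w1: float = 0.5
    w2: float = 0.5
    sigma_ref: float = 0.05   # reference COM sway (m)
    d_threshold: float = 0.10  # max allowable COM-BOS excursion (m)

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError("w1, w2 must be nonnegative and sum to 1")
        if self.sigma_ref <= 0 or self.d_threshold <= 0:
            raise ValueError("sigma_ref and d_threshold must be positive")


@dataclass(frozen=True)
class ErrorReport:
    category: str
    joints: tuple[int, ...]
    magnitude: float          # native units: degrees or meters
    severity: str
    frames: tuple[int, int]   # half-open interval
    corrective_key: str

    def __post_init__(self) -> None:
        if self.category not in ERROR_CATEGORIES:
            raise ValueError(f"unknown error category {self.category!r}")
        if self.severity not in SEVERITY_LEVELS:
            raise ValueError(f"unknown severity {self.severity!r}")


def severity_grade(deviation_deg: float) -> str:
    """Map an angular deviation (degrees) onto the rubric severity bands.

    <=5 within standard, <=10 minor, <=15 moderate, >15 severe; the lower
    band is inclusive at each boundary.  Monotone by construction.
    """
    if deviation_deg < 0:
        raise ValueError("deviation must be nonnegative")
    if deviation_deg <= 5.0:
        return "within_standard"
    if deviation_deg <= 10.0:
        return "minor"
    if deviation_deg <= 15.0:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# local joint frames and angular deviations


def _first_children(par: list[int]) -> dict[int, int]:
    child: dict[int, int] = {}
    for c, p in enumerate(par):
        if p >= 0 and p not in child:
            child[p] = c
    return child


def local_joint_rotations(
    seq: SkeletonSequence,
) -> list[list[UnitQuaternion | None]]:
    """Per-frame local joint rotations from the parent/child bone geometry.

    At joint j two Gram-Schmidt frames are built from the incoming bone
    direction u (p->j) and the outgoing bone direction v (j->c): F_in
    anchored on u (e1 = u, e2 = v orthogonalized against u) and F_out
    anchored on v (e1 = v, e2 = u orthogonalized against v).  The local
    rotation is q_j ~ F_in^T F_out.  Because a global rigid rotation
    premultiplies both frames, q_j is exactly invariant to whole-body
    motion, while its axis (the u/v bisector) tracks the bend: the
    deviation angle between two such rotations equals the flexion-angle
    difference for planar bends.  Bone-axis twist is not observable from
    joint positions and is not represented.  Joints with a missing
    relative, zero-length bones, or (anti)parallel bones (undefined bend
    plane) yield ``None`` — unavailable, never silently zero.
    """
    if seq.edges:
        par = [-1] * seq.n_joints
        for p, c in seq.edges:
            par[c] = p
    else:
        par = layout_parents(seq.joint_names)
    child = _first_children(par)
    out: list[list[UnitQuaternion | None]] = []
    for t in range(seq.n_frames):
        pos = seq.positions[t]
        row: list[UnitQuaternion | None] = []
        for j in range(seq.n_joints):
            p = par[j]
            c = child.get(j, -1)
            if p < 0 or c < 0:
                row.append(None)
                continue
            u = pos[j] - pos[p]
            v = pos[c] - pos[j]
            nu, nv = np.linalg.norm(u), np.linalg.norm(v)
            if nu < 1e-9 or nv < 1e-9:
                row.append(None)
                continue
            u = u / nu
            v = v / nv
            v_perp = v - (v @ u) * u
            u_perp = u - (u @ v) * v
            if np.linalg.norm(v_perp) < 1e-9 or np.linalg.norm(u_perp) < 1e-9:
                row.append(None)  # (anti)parallel bones: plane undefined
                continue
            e2_in = v_perp / np.linalg.norm(v_perp)
            e2_out = u_perp / np.linalg.norm(u_perp)
            f_in = np.stack([u, e2_in, np.cross(u, e2_in)], axis=1)
            f_out = np.stack([v, e2_out, np.cross(v, e2_out)], axis=1)
            row.append(
                UnitQuaternion.from_rotation(Rotation.from_matrix(f_in.T @ f_out))
            )
        out.append(row)
    return out


def _dtw_warp_reference(
    performed: SkeletonSequence, reference: SkeletonSequence
) -> SkeletonSequence:
    """Resample the reference onto the performed timeline via DTW."""
    from taijikit.segmentation import Template, dtw_align

    _, path = dtw_align(performed, Template("ref", reference))
    match = np.zeros(performed.n_frames, dtype=int)
    for i, j in path:
        match[i] = j  # last template frame matched to performed frame i
    return reference.slice_frames(0, reference.n_frames).with_positions(
        reference.positions[match]
    )


def joint_angle_deviations(
    performed: SkeletonSequence, reference: SkeletonSequence
) -> np.ndarray:
    """Per-frame, per-joint angular deviation dtheta in radians, NaN where
    the local rotation is unavailable.

    Sequences of different lengths are first aligned with DTW.
    """
    if performed.joint_names != reference.joint_names:
        raise ValueError("sequences must share a skeleton layout")
    if performed.n_frames != reference.n_frames:
        reference = _dtw_warp_reference(performed, reference)
    q_perf = local_joint_rotations(performed)
    q_ref = local_joint_rotations(reference)
    T, J = performed.n_frames, performed.n_joints
    out = np.full((T, J), np.nan)
    for t in range(T):
        for j in range(J):
            qp, qr = q_perf[t][j], q_ref[t][j]
            if qp is not None and qr is not None:
                out[t, j] = quaternion_angle(qr, qp)
    return out


def trajectory_error(
    performed_path: np.ndarray,
    reference_path: np.ndarray,
    cfg: TrajectoryErrorConfig = TrajectoryErrorConfig(),
    performed_vel: np.ndarray | None = None,
    reference_vel: np.ndarray | None = None,
) -> float:
    """E_traj = (1/T) sum_t sqrt(||p - p_ref||^2 + alpha ||v - v_ref||^2)."""
    p = np.asarray(performed_path, float)
    r = np.asarray(reference_path, float)
    if p.shape != r.shape:
        raise ValueError("paths must have equal (aligned) lengths")
    sq = np.sum((p - r) ** 2, axis=-1)
    if cfg.alpha_vel > 0:
        if performed_vel is None or reference_vel is None:
            vp = np.gradient(p, axis=0)
            vr = np.gradient(r, axis=0)
        else:
            vp = np.asarray(performed_vel, float)
            vr = np.asarray(reference_vel, float)
            if vp.shape != p.shape or vr.shape != r.shape:
                raise ValueError("velocity tracks must match path shapes")
        sq = sq + cfg.alpha_vel * np.sum((vp - vr) ** 2, axis=-1)
    return float(np.mean(np.sqrt(sq)))


def coordination_index(
    x_signals: list[np.ndarray],
    y_signals: list[np.ndarray],
    lag_fraction: float = 0.25,
) -> float:
    """C_coord: mean maximal normalized cross-correlation over signal pairs.

    For each paired signal the Pearson correlation of x(t) with y(t + tau)
    is maximized over lags |tau| <= ``lag_fraction`` of the length;
    zero-variance pairs are excluded with a warning.
    """
    vals = []
    for i, (x, y) in enumerate(zip(x_signals, y_signals)):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if np.std(x) < 1e-12 or np.std(y) < 1e-12:
            warnings.warn(f"pair {i} has zero variance; excluded", stacklevel=2)
            continue
        max_lag = max(int(lag_fraction * n), 1)
        best = -np.inf
        for tau in range(-max_lag, max_lag + 1):
            if tau >= 0:
                a, b = x[: n - tau], y[tau:]
            else:
                a, b = x[-tau:], y[: n + tau]
            if len(a) < 3 or np.std(a) < 1e-12 or np.std(b) < 1e-12:
                continue
            r = np.corrcoef(a, b)[0, 1]
            best = max(best, r)
        if np.isfinite(best):
            vals.append(best)
    if not vals:
        raise ValueError("no usable signal pairs for coordination index")
    return float(np.mean(vals))


def stability_metric(
    com_static: np.ndarray,
    com_dynamic: np.ndarray,
    polygon: SupportPolygon,
    cfg: StabilityConfig = StabilityConfig(),
) -> float:
    """S = w1 exp(-Var(COM_static)/sigma_ref^2) + w2 exp(-max_excursion/d_threshold).

    ``Var(COM_static)`` is the horizontal (ground-plane) sway variance of
    the static center-of-mass trace; the excursion term uses the maximal
    positive signed distance of the dynamic COM ground projection outside
    the base of support (clamped to 0 inside).
    """
    cs = np.asarray(com_static, float)
    cd = np.asarray(com_dynamic, float)
    if cs.size == 0 or cd.size == 0:
        raise ValueError("COM traces must be nonempty")
    xy = cs[:, :2]
    var = float(np.mean(np.sum((xy - xy.mean(axis=0)) ** 2, axis=1)))
    excursions = [max(0.0, point_to_polygon_distance(p, polygon)) for p in cd[:, :2]]
    d_max = max(excursions)
    return float(
        cfg.w1 * np.exp(-var / cfg.sigma_ref**2)
        + cfg.w2 * np.exp(-d_max / cfg.d_threshold)
    )


# ---------------------------------------------------------------------------
# rule-based error classification


@dataclass(frozen=True)
class CategoryThresholds:
    """Per-category firing thresholds in native units.

    Angular categories use the 5-degree rubric band; positional categories
    use equivalent metric scales.  ``sustain_s`` is the minimum duration a
    deviation must persist to count as an error rather than a spike.
    """

    weight_distribution: float = 0.2    # balance-index fraction
    spine_alignment: float = 5.0        # degrees
    arm_extension: float = 5.0          # degrees
    knee_position: float = 0.03         # meters past the toe line
    hip_rotation: float = 5.0           # degrees of yaw deviation
    shoulder_tension: float = 0.02      # meters of shoulder raise
    sustain_s: float = 0.5

    def get(self, category: str) -> float:
        return getattr(self, category)


def _idx(seq: SkeletonSequence, name: str) -> int:
    return seq.joint_names.index(name)


def _balance_index(seq: SkeletonSequence) -> np.ndarray:
    """Per-frame (W_L - W_R) / (W_L + W_R) from the COM / ankle geometry.

    Foot weights are proxied by the position of the COM ground projection
    along the inter-ankle line (no force plates: the closer foot bears
    proportionally more weight).  Replaceable estimator.
    """
    com = center_of_mass(seq.positions, np.ones(seq.n_joints))[:, :2]
    al = seq.positions[:, _idx(seq, "ankle_l"), :2]
    ar = seq.positions[:, _idx(seq, "ankle_r"), :2]
    axis = al - ar
    sep_sq = np.maximum(np.sum(axis**2, axis=1), 1e-12)
    t = np.clip(np.sum((com - ar) * axis, axis=1) / sep_sq, 0.0, 1.0)
    return 2.0 * t - 1.0  # w_L = t, w_R = 1 - t


def foot_weights(seq: SkeletonSequence) -> np.ndarray:
    """(T, 2) left/right foot-weight shares from the COM proxy."""
    b = _balance_index(seq)
    return np.stack([(1 + b) / 2, (1 - b) / 2], axis=1)


def _spine_angle_deg(seq: SkeletonSequence) -> np.ndarray:
    """Per-frame spine inclination from vertical, degrees."""
    axis = (
        seq.positions[:, _idx(seq, "neck")] - seq.positions[:, _idx(seq, "pelvis")]
    )
    axis = axis / np.maximum(np.linalg.norm(axis, axis=1, keepdims=True), 1e-9)
    return np.degrees(np.arccos(np.clip(axis[:, 2], -1.0, 1.0)))


def _elbow_angles_deg(seq: SkeletonSequence) -> np.ndarray:
    out = []
    for side in ("l", "r"):
        s = seq.positions[:, _idx(seq, f"shoulder_{side}")]
        e = seq.positions[:, _idx(seq, f"elbow_{side}")]
        w = seq.positions[:, _idx(seq, f"wrist_{side}")]
        u = s - e
        v = w - e
        cosang = np.sum(u * v, axis=1) / np.maximum(
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1), 1e-9
        )
        out.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.stack(out, axis=1)  # (T, 2)


def _knee_past_toe_m(seq: SkeletonSequence) -> np.ndarray:
    out = []
    for side in ("l", "r"):
        knee = seq.positions[:, _idx(seq, f"knee_{side}"), :2]
        ankle = seq.positions[:, _idx(seq, f"ankle_{side}"), :2]
        toe = seq.positions[:, _idx(seq, f"foot_{side}"), :2]
        axis = toe - ankle
        axis = axis / np.maximum(np.linalg.norm(axis, axis=1, keepdims=True), 1e-9)
        # signed distance of the knee projection past the toe along the foot axis
        out.append(np.sum((knee - toe) * axis, axis=1))
    return np.stack(out, axis=1)


def _pelvis_yaw_deg(seq: SkeletonSequence) -> np.ndarray:
    axis = (
        seq.positions[:, _idx(seq, "hip_r"), :2]
        - seq.positions[:, _idx(seq, "hip_l"), :2]
    )
    return np.degrees(np.arctan2(axis[:, 1], axis[:, 0]))


def _angle_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|a - b| on the circle, in [0, 180] degrees."""
    return np.abs((a - b + 180.0) % 360.0 - 180.0)


def _shoulder_raise_m(seq: SkeletonSequence) -> np.ndarray:
    neck_z = seq.positions[:, _idx(seq, "neck"), 2]
    zl = seq.positions[:, _idx(seq, "shoulder_l"), 2]
    zr = seq.positions[:, _idx(seq, "shoulder_r"), 2]
    return np.stack([zl - neck_z, zr - neck_z], axis=1)


def _sustained_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    runs = []
    start = None
    for t, m in enumerate(mask):
        if m and start is None:
            start = t
        elif not m and start is not None:
            if t - start >= min_len:
                runs.append((start, t))
            start = None
    if start is not None and len(mask) - start >= min_len:
        runs.append((start, len(mask)))
    return runs


def _category_signals(
    performed: SkeletonSequence, reference: SkeletonSequence
) -> dict[str, tuple[np.ndarray, tuple[int, ...]]]:
    """Per-category (per-frame deviation signal, involved joint indices)."""
    sig: dict[str, tuple[np.ndarray, tuple[int, ...]]] = {}

    def joints(*names: str) -> tuple[int, ...]:
        return tuple(_idx(performed, n) for n in names)

    sig["weight_distribution"] = (
        np.abs(_balance_index(performed) - _balance_index(reference)),
        joints("ankle_l", "ankle_r", "pelvis"),
    )
    sig["spine_alignment"] = (
        np.abs(_spine_angle_deg(performed) - _spine_angle_deg(reference)),
        joints("pelvis", "spine_02", "neck"),
    )
    sig["arm_extension"] = (
        np.abs(_elbow_angles_deg(performed) - _elbow_angles_deg(reference)).max(axis=1),
        joints("elbow_l", "elbow_r"),
    )
    sig["knee_position"] = (
        np.maximum(
            _knee_past_toe_m(performed) - _knee_past_toe_m(reference), 0.0
        ).max(axis=1),
        joints("knee_l", "knee_r"),
    )
    sig["hip_rotation"] = (
        _angle_diff_deg(_pelvis_yaw_deg(performed), _pelvis_yaw_deg(reference)),
        joints("hip_l", "hip_r", "pelvis"),
    )
    sig["shoulder_tension"] = (
        (_shoulder_raise_m(performed) - _shoulder_raise_m(reference)).max(axis=1),
        joints("shoulder_l", "shoulder_r"),
    )
    return sig


def classify_errors(
    performed: SkeletonSequence,
    reference: SkeletonSequence,
    thresholds: CategoryThresholds = CategoryThresholds(),
) -> list[ErrorReport]:
    """Rule-based error classification against a reference replay.

    One rule per category fires when its deviation signal exceeds the
    category threshold over a sustained window (>= ``sustain_s`` seconds).
    Reports are sorted by threshold-normalized magnitude, most significant
    first.  A clean replay yields an empty list.
    """
    if performed.joint_names != reference.joint_names:
        raise ValueError("sequences must share a skeleton layout")
    if performed.n_frames != reference.n_frames:
        reference = _dtw_warp_reference(performed, reference)
    min_len = max(int(round(thresholds.sustain_s * performed.fps)), 1)
    reports: list[ErrorReport] = []
    for category in ERROR_CATEGORIES:
        try:
            signal, joints = _category_signals(performed, reference)[category]
        except (ValueError, KeyError) as exc:
            warnings.warn(
                f"category {category}: missing derived quantity ({exc}); skipped",
                stacklevel=2,
            )
            continue
        thr = thresholds.get(category)
        runs = _sustained_runs(signal > thr, min_len)
        if not runs:
            continue
        start = min(r[0] for r in runs)
        end = max(r[1] for r in runs)
        magnitude = float(max(signal[a:b].max() for a, b in runs))
        # grade on the rubric bands, rescaled to this category's units
        severity = severity_grade(5.0 * magnitude / thr)
        reports.append(
            ErrorReport(
                category=category,
                joints=joints,
                magnitude=magnitude,
                severity=severity,
                frames=(start, end),
                corrective_key=f"correct_{category}",
            )
        )
    reports.sort(key=lambda r: r.magnitude / thresholds.get(r.category), reverse=True)
    return reports
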