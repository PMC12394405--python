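"""Core skeleton data model and kinematic primitives.

The universal currency of the toolkit is the :class:`SkeletonSequence`:
an ordered stack of frames, each holding J joints in world coordinates
(meters), with per-joint confidences and a frame rate.  On top of it sit
central-difference kinematic derivatives, quaternion geodesic angles
(gimbal-lock-free joint rotation comparison), a mass-weighted center of
mass, and base-of-support geometry on the ground plane (world z = 0).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.transform import Rotation
from shapely.geometry import Point, Polygon

__all__ = [
    "SkeletonSequence",
    "KinematicDerivatives",
    "UnitQuaternion",
    "SupportPolygon",
    "central_velocity",
    "central_acceleration",
    "quaternion_angle",
    "center_of_mass",
    "support_polygon",
    "point_to_polygon_distance",
]


@dataclass(frozen=True)
class SkeletonSequence:
    """Frames x joints x 3 world coordinates with confidences and frame rate.

    Parameters
    ----------
    positions : ndarray, shape (T, J, 3)
        Joint positions in meters. Must be finite.
    confidence : ndarray, shape (T, J)
        Per-joint detection confidence in [0, 1].
    fps : float
        Frames per second, > 0.
    joint_names : tuple of str
        Ordered joint labels, length J.
    edges : tuple of (int, int)
        Physical skeleton connectivity as joint-index pairs.
    """

    positions: np.ndarray
    confidence: np.ndarray
    fps: float
    joint_names: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise ValueError(f"positions must be (frames, joints, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        conf = np.asarray(self.confidence, dtype=float)
        if conf.shape != pos.shape[:2]:
            raise ValueError(
                f"confidence shape {conf.shape} does not match positions {pos.shape[:2]}"
            )
        if np.any(conf < 0) or np.any(conf > 1):
            raise ValueError("confidence must lie in [0, 1]")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        if len(self.joint_names) != pos.shape[1]:
            raise ValueError("joint_names length must equal joint count")
        for i, j in self.edges:
            if not (0 <= i < pos.shape[1] and 0 <= j < pos.shape[1]):
                raise ValueError(f"edge ({i}, {j}) references invalid joint index")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "confidence", conf)
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        object.__setattr__(self, "joint_names", tuple(self.joint_names))

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_joints(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    def slice_frames(self, start: int, end: int) -> "SkeletonSequence":
        """Half-open frame slice [start, end) as a new sequence."""
        return dataclasses.replace(
            self,
            positions=self.positions[start:end],
            confidence=self.confidence[start:end],
        )

    def with_positions(self, positions: np.ndarray) -> "SkeletonSequence":
        return dataclasses.replace(self, positions=np.asarray(positions, float))


@dataclass(frozen=True)
class KinematicDerivatives:
    """Central-difference velocity/acceleration tracks of a sequence."""

    velocity: np.ndarray | None
    acceleration: np.ndarray | None
    dt: float

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")


def _central_difference(x: np.ndarray, dt: float) -> np.ndarray:
    """Symmetric central difference on interior frames, one-sided at the ends.

    Preserves the frame count of the input track.
    """
    out = np.empty_like(x)
    out[1:-1] = (x[2:] - x[:-2]) / (2.0 * dt)
    out[0] = (x[1] - x[0]) / dt
    out[-1] = (x[-1] - x[-2]) / dt
    return out


def central_velocity(seq: SkeletonSequence) -> KinematicDerivatives:
    """Per-joint velocity v_j(t) = (p_j(t+dt) - p_j(t-dt)) / (2 dt), m/s.

    Interior frames use the symmetric central difference over +-1 frame;
    the two endpoint frames fall back to one-sided first differences so the
    output has the same length as the input.
    """
    if seq.n_frames < 3:
        raise ValueError(
            f"central_velocity requires at least 3 frames, got {seq.n_frames}"
        )
    return KinematicDerivatives(
        velocity=_central_difference(seq.positions, seq.dt),
        acceleration=None,
        dt=seq.dt,
    )


def central_acceleration(deriv: KinematicDerivatives) -> KinematicDerivatives:
    """Acceleration a_j(t) as the central difference of the velocity track."""
    if deriv.velocity is None:
        raise ValueError("central_acceleration requires a velocity track")
    if deriv.velocity.shape[0] < 3:
        raise ValueError("central_acceleration requires at least 3 frames")
    return KinematicDerivatives(
        velocity=deriv.velocity,
        acceleration=_central_difference(deriv.velocity, deriv.dt),
        dt=deriv.dt,
    )


_UNIT_TOL = 1e-6


@dataclass(frozen=True)
class UnitQuaternion:
    """Unit quaternion (w, x, y, z) representing a 3D rotation."""

    w: float
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        n = np.sqrt(self.w**2 + self.x**2 + self.y**2 + self.z**2)
        if abs(n - 1.0) > _UNIT_TOL:
            raise ValueError(f"quaternion norm {n:.3g} is not 1 within tolerance")

    @classmethod
    def from_array(cls, q: np.ndarray, normalize: bool = False) -> "UnitQuaternion":
        q = np.asarray(q, dtype=float)
        if normalize:
            q = q / np.linalg.norm(q)
        return cls(*q)

    @classmethod
    def from_rotation(cls, rot: Rotation) -> "UnitQuaternion":
        x, y, z, w = rot.as_quat()
        return cls(w, x, y, z)

    def as_array(self) -> np.ndarray:
        return np.array([self.w, self.x, self.y, self.z])

    def as_rotation(self) -> Rotation:
        return Rotation.from_quat([self.x, self.y, self.z, self.w])


def quaternion_angle(q_ref: UnitQuaternion, q_perf: UnitQuaternion) -> float:
    """Geodesic angle dtheta = 2 arccos(|q_ref . q_perf|), radians in [0, pi].

    The absolute value of the dot product makes the angle invariant to the
    quaternion double cover (q and -q encode the same rotation).  Evaluated
    through the chord identity theta = 4 asin(min(|q - q'|, |q + q'|) / 2),
    which is algebraically identical but numerically exact near zero where
    arccos loses half the significant digits.
    """
    a = q_ref.as_array()
    b = q_perf.as_array()
    chord = min(float(np.linalg.norm(a - b)), float(np.linalg.norm(a + b)))
    return float(4.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0)))


def center_of_mass(positions: np.ndarray, segment_masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean of joint positions for one frame (or many).

    ``positions`` is (J, 3) or (T, J, 3); masses are nonnegative per joint
    with a positive sum.  With uniform masses this is the joint centroid; a
    per-joint anthropometric table can be supplied instead.
    """
    m = np.asarray(segment_masses, dtype=float)
    if np.any(m < 0):
        raise ValueError("segment masses must be nonnegative")
    total = m.sum()
    if not total > 0:
        raise ValueError("segment masses must have positive sum")
    pos = np.asarray(positions, dtype=float)
    return (pos * m[..., :, None]).sum(axis=-2) / total


@dataclass(frozen=True)
class SupportPolygon:
    """Convex base-of-support region on the ground plane (z = 0).

    Vertices are ordered counter-clockwise and define a non-degenerate
    convex polygon.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("SupportPolygon needs >= 3 two-dimensional vertices")
        # shoelace area > 0 iff counter-clockwise and non-degenerate
        x, y = v[:, 0], v[:, 1]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area <= 1e-12:
            raise ValueError("degenerate support: vertices collinear or clockwise")
        object.__setattr__(self, "vertices", v)

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


def support_polygon(foot_contact_points: np.ndarray) -> SupportPolygon:
    """Convex hull of ground-plane foot contact points (x, y in meters).

    3D points are projected onto the ground plane by dropping z.  Fewer than
    three distinct non-collinear points raise ``degenerate support``.
    """
    pts = np.asarray(foot_contact_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("degenerate support: need at least 3 contact points")
    if pts.shape[1] == 3:
        pts = pts[:, :2]
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate support: contact points are collinear") from exc
    return SupportPolygon(vertices=pts[hull.vertices])  # qhull: CCW in 2D


def point_to_polygon_distance(point: np.ndarray, polygon: SupportPolygon) -> float:
    """Signed distance from a ground-plane point to the polygon boundary.

    Negative strictly inside, zero on the boundary, positive outside.
    """
    p = Point(np.asarray(point, dtype=float)[:2])
    poly = polygon.as_shapely()
    d = p.distance(poly.exterior)
    return -d if poly.contains(p) else d
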