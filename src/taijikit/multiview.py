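"""Camera geometry and multi-view 3D reconstruction.

Pinhole cameras are parameterized by intrinsics K, a world-to-camera
rotation R and the camera center C in world coordinates, giving the
projection P = K R [I | -C].  Joint positions are recovered by
confidence-weighted triangulation

    X_3D = argmin_X  sum_i  w_i * || P_i X - x_i ||^2   (pixel distance)

initialized by a weighted linear DLT and refined with Gauss-Newton steps.
Whole sequences are reconstructed under the composite objective

    E_total = E_data + lambda_1 * E_smooth + lambda_2 * E_prior

where E_smooth is the summed squared frame-to-frame joint displacement
(temporal coherence) and E_prior is a hinge penalty on joint bend angles
outside configured limits (movement-plausibility constraints), minimized
by block-coordinate descent over frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from taijikit.skeleton import SkeletonSequence

__all__ = [
    "CameraModel",
    "Observation2D",
    "ReconstructionConfig",
    "FusionConfig",
    "IllConditionedWarning",
    "joint_confidence",
    "fuse_features",
    "camera_transform",
    "compose_transforms",
    "apply_transform",
    "project",
    "triangulate_weighted",
    "reconstruct_sequence",
]


class IllConditionedWarning(UserWarning):
    """Raised (as a warning) when triangulation rays are near-parallel."""


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera: intrinsics K, rotation R (world->camera), center C."""

    K: np.ndarray
    R: np.ndarray
    C: np.ndarray
    cam_id: str = "cam"

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        R = np.asarray(self.R, dtype=float)
        C = np.asarray(self.C, dtype=float).reshape(3)
        if K.shape != (3, 3) or R.shape != (3, 3):
            raise ValueError("K and R must be 3x3")
        if abs(K[1, 0]) > 1e-12 or abs(K[2, 0]) > 1e-12 or abs(K[2, 1]) > 1e-12:
            raise ValueError("K must be upper-triangular")
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ValueError("focal entries of K must be positive")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("R must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("R must have determinant +1")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "C", C)

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K R [I | -C]."""
        return self.K @ self.R @ np.hstack([np.eye(3), -self.C[:, None]])


@dataclass(frozen=True)
class Observation2D:
    """A single-view 2D joint observation with detection confidence."""

    view_id: str
    pixel: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixel, dtype=float).reshape(2)
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel must be finite")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        object.__setattr__(self, "pixel", px)


@dataclass(frozen=True)
class FusionConfig:
    """Modality mixing weight for RGB/depth feature fusion."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class ReconstructionConfig:
    """Weights and limits for the regularized sequence reconstruction."""

    lambda_smooth: float = 0.0
    lambda_prior: float = 0.0
    # joint index -> (min, max) bend angle in radians, measured at the joint
    # between its parent and child bones
    joint_angle_limits: dict = field(default_factory=dict)
    max_iterations: int = 20
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.lambda_smooth < 0 or self.lambda_prior < 0:
            raise ValueError("regularization weights must be >= 0")
        for j, (lo, hi) in self.joint_angle_limits.items():
            if lo > hi:
                raise ValueError(f"angle limits for joint {j} are not ordered")


def joint_confidence(heatmap: np.ndarray, region: np.ndarray) -> float:
    """Detection confidence C_j: mean heatmap response over a local region.

    ``region`` is an (n, 2) array of (row, col) pixel indices.
    """
    hm = np.asarray(heatmap, dtype=float)
    reg = np.asarray(region, dtype=int)
    if reg.size == 0:
        raise ValueError("region must be nonempty")
    reg = reg.reshape(-1, 2)
    if (
        np.any(reg < 0)
        or np.any(reg[:, 0] >= hm.shape[0])
        or np.any(reg[:, 1] >= hm.shape[1])
    ):
        raise ValueError("region indices out of heatmap bounds")
    return float(hm[reg[:, 0], reg[:, 1]].mean())


def fuse_features(
    f_rgb: np.ndarray, f_depth: np.ndarray, cfg: FusionConfig
) -> np.ndarray:
    """Convex combination F = alpha * F_rgb + (1 - alpha) * F_depth."""
    a = np.asarray(f_rgb, dtype=float)
    b = np.asarray(f_depth, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"feature length mismatch: {a.shape} vs {b.shape}")
    return cfg.alpha * a + (1.0 - cfg.alpha) * b


def camera_transform(cam_i: CameraModel, cam_j: CameraModel) -> np.ndarray:
    """3x4 transform T_{i->j} = R_ij [I | -C_i], with R_ij = R_j R_i^T.

    Applied to a homogeneous world point X it yields R_ij (X - C_i): the
    offset from camera i's center, re-oriented by the relative rotation
    between the two cameras.  For cam_i == cam_j the relative rotation is
    the identity and camera-centered points map to themselves.
    """
    R_ij = cam_j.R @ cam_i.R.T
    return R_ij @ np.hstack([np.eye(3), -cam_i.C[:, None]])


def compose_transforms(t_jk: np.ndarray, t_ij: np.ndarray) -> np.ndarray:
    """Chain T_{i->j} then T_{j->k} into T_{i->k}.

    Only the rotation block of the second transform participates: the
    translation column of these transforms is anchored at the *source*
    camera center, so T_{i->k} keeps the first transform's anchor while
    accumulating rotation.
    """
    return t_jk[:, :3] @ t_ij


def apply_transform(t: np.ndarray, x_world: np.ndarray) -> np.ndarray:
    """Apply a 3x4 transform to a 3D world point."""
    xh = np.append(np.asarray(x_world, dtype=float), 1.0)
    return t @ xh


def project(cam: CameraModel, x: np.ndarray) -> np.ndarray:
    """Pinhole projection of a world point to pixel coordinates.

    Rejects points with nonpositive depth in the camera frame.
    """
    x = np.asarray(x, dtype=float).reshape(3)
    xc = cam.R @ (x - cam.C)
    if xc[2] <= 0:
        raise ValueError("behind camera: point has nonpositive depth")
    uvw = cam.K @ xc
    return uvw[:2] / uvw[2]


def _dlt(
    pixels: np.ndarray, weights: np.ndarray, pmats: list[np.ndarray]
) -> tuple[np.ndarray, float]:
    """Weighted linear DLT initialization; returns point and condition metric."""
    rows = []
    for (u, v), w, P in zip(pixels, weights, pmats):
        sw = np.sqrt(w)
        rows.append(sw * (u * P[2] - P[0]))
        rows.append(sw * (v * P[2] - P[1]))
    A = np.array(rows)
    _, s, vt = np.linalg.svd(A)
    X = vt[-1]
    if abs(X[3]) < 1e-12:
        raise ValueError("ill-conditioned: point at infinity in DLT solution")
    cond = s[-2] / s[0] if s[0] > 0 else 0.0  # second-smallest sv gauges rays
    return X[:3] / X[3], float(cond)


def triangulate_weighted(
    observations: list[Observation2D],
    cameras: dict[str, CameraModel] | list[CameraModel],
    max_iter: int = 10,
    tol: float = 1e-12,
) -> tuple[np.ndarray, float]:
    """Confidence-weighted triangulation of one 3D point.

    Minimizes sum_i w_i ||P_i X - x_i||^2 over world points X: a weighted
    linear DLT start followed by Gauss-Newton refinement on the pixel
    reprojection residuals.  Returns ``(X, residual)`` where residual is the
    achieved weighted squared reprojection error.

    Raises ``ValueError("underdetermined")`` with fewer than two positively
    weighted views and warns :class:`IllConditionedWarning` when the view
    rays are near-parallel.
    """
    if isinstance(cameras, dict):
        cam_of = cameras
    else:
        cam_of = {c.cam_id: c for c in cameras}
    usable = [o for o in observations if o.weight > 0]
    if len(usable) < 2:
        raise ValueError("underdetermined: need >= 2 views with positive weight")
    pixels = np.array([o.pixel for o in usable])
    weights = np.array([o.weight for o in usable])
    cams = [cam_of[o.view_id] for o in usable]
    pmats = [c.P for c in cams]

    X, cond = _dlt(pixels, weights, pmats)
    if cond < 1e-6:
        warnings.warn(
            f"ill-conditioned triangulation (ray condition {cond:.2e})",
            IllConditionedWarning,
            stacklevel=2,
        )

    KRs = [c.K @ c.R for c in cams]
    kts = [-(kr @ c.C) for kr, c in zip(KRs, cams)]

    def residuals_and_jac(X: np.ndarray):
        res = []
        jac = []
        for (u, v), w, KR, kt in zip(pixels, weights, KRs, kts):
            xc = KR @ X + kt
            z = xc[2]
            r = np.array([xc[0] / z - u, xc[1] / z - v])
            # d(x/z)/dX = (z * dx - x * dz) / z^2
            J = np.empty((2, 3))
            J[0] = (z * KR[0] - xc[0] * KR[2]) / z**2
            J[1] = (z * KR[1] - xc[1] * KR[2]) / z**2
            sw = np.sqrt(w)
            res.append(sw * r)
            jac.append(sw * J)
        return np.concatenate(res), np.vstack(jac)

    prev = np.inf
    for _ in range(max_iter):
        r, J = residuals_and_jac(X)
        cost = float(r @ r)
        if abs(prev - cost) < tol:
            break
        prev = cost
        try:
            step = np.linalg.lstsq(J, -r, rcond=None)[0]
        except np.linalg.LinAlgError:
            break
        X = X + step
    r, _ = residuals_and_jac(X)
    return X, float(r @ r)


def _reprojection_cost(
    X: np.ndarray, pixels: np.ndarray, weights: np.ndarray, cams: list[CameraModel]
) -> float:
    c = 0.0
    for (u, v), w, cam in zip(pixels, weights, cams):
        xc = cam.K @ (cam.R @ (X - cam.C))
        px = xc[:2] / xc[2]
        c += w * ((px[0] - u) ** 2 + (px[1] - v) ** 2)
    return c


def _bend_angles(pos: np.ndarray, limits: dict, edges) -> dict[int, float]:
    """Bend angle at each limited joint between parent and child bones."""
    parent = {}
    child = {}
    for p, c in edges:
        child.setdefault(p, c)
        parent[c] = p
    out = {}
    for j in limits:
        if j not in parent or j not in child:
            continue
        u = pos[parent[j]] - pos[j]
        v = pos[child[j]] - pos[j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            continue
        out[j] = float(np.arccos(np.clip(u @ v / (nu * nv), -1.0, 1.0)))
    return out


def _prior_penalty(pos: np.ndarray, cfg: ReconstructionConfig, edges) -> float:
    """Hinge penalty sum max(0, th - th_max)^2 + max(0, th_min - th)^2."""
    if not cfg.joint_angle_limits:
        return 0.0
    pen = 0.0
    for j, th in _bend_angles(pos, cfg.joint_angle_limits, edges).items():
        lo, hi = cfg.joint_angle_limits[j]
        pen += max(0.0, th - hi) ** 2 + max(0.0, lo - th) ** 2
    return pen


def reconstruction_objective(
    positions: np.ndarray,
    frames_obs: list[dict[int, list[Observation2D]]],
    cameras: dict[str, CameraModel],
    cfg: ReconstructionConfig,
    edges=(),
) -> float:
    """E_total = E_data + lambda_1 E_smooth + lambda_2 E_prior."""
    e_data = 0.0
    for t, obs_by_joint in enumerate(frames_obs):
        for j, obs in obs_by_joint.items():
            usable = [o for o in obs if o.weight > 0]
            if not usable:
                continue
            pixels = np.array([o.pixel for o in usable])
            weights = np.array([o.weight for o in usable])
            cams = [cameras[o.view_id] for o in usable]
            e_data += _reprojection_cost(positions[t, j], pixels, weights, cams)
    e_smooth = float(np.sum((positions[1:] - positions[:-1]) ** 2))
    e_prior = sum(_prior_penalty(positions[t], cfg, edges) for t in range(len(positions)))
    return e_data + cfg.lambda_smooth * e_smooth + cfg.lambda_prior * e_prior


def reconstruct_sequence(
    frames_obs: list[dict[int, list[Observation2D]]],
    cameras: dict[str, CameraModel] | list[CameraModel],
    cfg: ReconstructionConfig,
    fps: float = 30.0,
    joint_names: tuple[str, ...] | None = None,
    edges: tuple[tuple[int, int], ...] = (),
) -> SkeletonSequence:
    """Reconstruct a 3D skeleton sequence from per-frame 2D observations.

    ``frames_obs[t][j]`` is the list of :class:`Observation2D` for joint j at
    frame t.  Per-frame weighted triangulation provides the initialization;
    with ``lambda_smooth`` or ``lambda_prior`` positive, block-coordinate
    descent over frames then minimizes E_total, guaranteeing a monotonically
    non-increasing objective.  Raises on divergence.
    """
    if isinstance(cameras, list):
        cameras = {c.cam_id: c for c in cameras}
    T = len(frames_obs)
    joints = sorted({j for f in frames_obs for j in f})
    J = (max(joints) + 1) if joints else 0
    positions = np.zeros((T, J, 3))
    for t, obs_by_joint in enumerate(frames_obs):
        for j in range(J):
            obs = obs_by_joint.get(j, [])
            try:
                positions[t, j], _ = triangulate_weighted(obs, cameras)
            except ValueError:
                # fall back to previous frame for unobservable joints
                positions[t, j] = positions[t - 1, j] if t > 0 else 0.0

    if cfg.lambda_smooth > 0 or cfg.lambda_prior > 0:
        positions = _coordinate_descent(positions, frames_obs, cameras, cfg, edges)

    J_out = positions.shape[1]
    names = joint_names or tuple(f"j{i}" for i in range(J_out))
    return SkeletonSequence(
        positions=positions,
        confidence=np.ones((T, J_out)),
        fps=fps,
        joint_names=names,
        edges=edges,
    )


def _frame_cost(
    x_flat: np.ndarray,
    t: int,
    positions: np.ndarray,
    frames_obs,
    cameras,
    cfg: ReconstructionConfig,
    edges,
) -> float:
    J = positions.shape[1]
    pos_t = x_flat.reshape(J, 3)
    c = 0.0
    for j, obs in frames_obs[t].items():
        usable = [o for o in obs if o.weight > 0]
        if not usable:
            continue
        pixels = np.array([o.pixel for o in usable])
        weights = np.array([o.weight for o in usable])
        cams = [cameras[o.view_id] for o in usable]
        c += _reprojection_cost(pos_t[j], pixels, weights, cams)
    if cfg.lambda_smooth > 0:
        if t > 0:
            c += cfg.lambda_smooth * float(np.sum((pos_t - positions[t - 1]) ** 2))
        if t < len(positions) - 1:
            c += cfg.lambda_smooth * float(np.sum((positions[t + 1] - pos_t) ** 2))
    if cfg.lambda_prior > 0:
        c += cfg.lambda_prior * _prior_penalty(pos_t, cfg, edges)
    return c


def _coordinate_descent(
    positions: np.ndarray, frames_obs, cameras, cfg: ReconstructionConfig, edges
) -> np.ndarray:
    prev_total = reconstruction_objective(positions, frames_obs, cameras, cfg, edges)
    for _ in range(cfg.max_iterations):
        for t in range(len(positions)):
            x0 = positions[t].ravel()
            res = minimize(
                _frame_cost,
                x0,
                args=(t, positions, frames_obs, cameras, cfg, edges),
                method="L-BFGS-B",
                options={"maxiter": 30},
            )
            # keep the update only if the frame objective did not worsen
            if res.fun <= _frame_cost(
                x0, t, positions, frames_obs, cameras, cfg, edges
            ):
                positions[t] = res.x.reshape(positions[t].shape)
        total = reconstruction_objective(positions, frames_obs, cameras, cfg, edges)
        if total > prev_total + 1e-6 * (1.0 + abs(prev_total)):
            raise RuntimeError(
                f"reconstruction diverged: objective rose from {prev_total:.6g} "
                f"to {total:.6g}"
            )
        if prev_total - total < cfg.convergence_tol * (1.0 + abs(prev_total)):
            break
        prev_total = total
    return positions
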