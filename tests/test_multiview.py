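"""Camera geometry, feature fusion and weighted triangulation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from taijikit.multiview import (
    CameraModel,
    FusionConfig,
    Observation2D,
    ReconstructionConfig,
    apply_transform,
    camera_transform,
    compose_transforms,
    fuse_features,
    joint_confidence,
    project,
    reconstruct_sequence,
    reconstruction_objective,
    triangulate_weighted,
)


def random_camera(rng, cam_id="cam"):
    R = Rotation.random(random_state=int(rng.integers(2**31 - 1))).as_matrix()
    C = rng.normal(scale=2.0, size=3)
    K = np.array([[800.0, 0, 320], [0, 800.0, 240], [0, 0, 1]])
    return CameraModel(K=K, R=R, C=C, cam_id=cam_id)


class TestConfidenceAndFusion:
    def test_constant_heatmap(self):
        hm = np.full((8, 8), 0.7)
        region = np.array([[1, 1], [2, 3], [4, 4]])
        assert joint_confidence(hm, region) == pytest.approx(0.7)

    def test_single_pixel(self, rng):
        hm = rng.uniform(size=(8, 8))
        assert joint_confidence(hm, np.array([[3, 5]])) == hm[3, 5]

    def test_mean_oracle(self, rng):
        hm = rng.uniform(size=(16, 16))
        flat = rng.choice(256, size=10, replace=False)
        region = np.stack([flat // 16, flat % 16], axis=1)
        oracle = sum(hm[r, c] for r, c in region) / len(region)
        assert joint_confidence(hm, region) == pytest.approx(oracle, abs=1e-12)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            joint_confidence(np.ones((4, 4)), np.empty((0, 2)))

    @pytest.mark.parametrize(
        "alpha,expected",
        [(1.0, [2.0, 4.0]), (0.0, [0.0, 0.0]), (0.5, [1.0, 2.0])],
    )
    def test_fusion_convex_combination(self, alpha, expected):
        out = fuse_features([2.0, 4.0], [0.0, 0.0], FusionConfig(alpha=alpha))
        assert np.allclose(out, expected)

    def test_fusion_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_features([1.0], [1.0, 2.0], FusionConfig())


class TestCameraTransform:
    def test_same_camera_is_identity_on_centered_points(self, rng):
        cam = random_camera(rng)
        t = camera_transform(cam, cam)
        offset = rng.normal(size=3)
        assert np.allclose(apply_transform(t, cam.C + offset), offset)

    def test_origin_identity(self):
        K = np.eye(3)
        cam = CameraModel(K=K, R=np.eye(3), C=np.zeros(3))
        t = camera_transform(cam, cam)
        assert np.allclose(t, np.hstack([np.eye(3), np.zeros((3, 1))]))

    def test_matrix_product_oracle(self, rng):
        cam_i = random_camera(rng, "i")
        cam_j = random_camera(rng, "j")
        t = camera_transform(cam_i, cam_j)
        oracle = (cam_j.R @ cam_i.R.T) @ np.hstack(
            [np.eye(3), -cam_i.C[:, None]]
        )
        assert np.abs(t - oracle).max() < 1e-10
        for _ in range(50):
            x = rng.normal(size=3)
            assert np.allclose(
                apply_transform(t, x),
                cam_j.R @ cam_i.R.T @ (x - cam_i.C),
                atol=1e-10,
            )

    def test_composition(self, rng):
        cams = [random_camera(rng, k) for k in "ijk"]
        t_ij = camera_transform(cams[0], cams[1])
        t_jk = camera_transform(cams[1], cams[2])
        t_ik = camera_transform(cams[0], cams[2])
        assert np.allclose(compose_transforms(t_jk, t_ij), t_ik, atol=1e-12)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError, match="orthonormal"):
            CameraModel(K=np.eye(3), R=np.eye(3) * 2, C=np.zeros(3))


class TestProjection:
    def test_optical_axis_hits_principal_point(self):
        K = np.array([[500.0, 0, 100], [0, 500.0, 80], [0, 0, 1]])
        cam = CameraModel(K=K, R=np.eye(3), C=np.zeros(3))
        assert np.allclose(project(cam, [0, 0, 3.0]), [100, 80])

    def test_unit_focal_offset(self):
        cam = CameraModel(K=np.eye(3), R=np.eye(3), C=np.zeros(3))
        assert np.allclose(project(cam, [1.0, 0, 1.0]), [1.0, 0.0])

    def test_behind_camera_rejected(self):
        cam = CameraModel(K=np.eye(3), R=np.eye(3), C=np.zeros(3))
        with pytest.raises(ValueError, match="behind camera"):
            project(cam, [0, 0, -1.0])

    def test_ray_roundtrip_oracle(self, rng):
        for _ in range(10):
            cam = random_camera(rng)
            x = cam.C + cam.R.T @ (rng.normal(size=3) + [0, 0, 5.0])
            px = project(cam, x)
            # cast the pixel ray back into the world and re-intersect X
            d_cam = np.linalg.solve(cam.K, np.append(px, 1.0))
            d_world = cam.R.T @ d_cam
            depth = (cam.R @ (x - cam.C))[2]
            reconstructed = cam.C + d_world * depth
            assert np.linalg.norm(reconstructed - x) < 1e-9


def ring(n=4, radius=3.0):
    from taijikit.synth import camera_ring

    return camera_ring(n_cameras=n, radius=radius)


def observe(cams, x, weights=None, noise=None):
    obs = []
    for k, cam in enumerate(cams):
        px = project(cam, x)
        if noise is not None:
            px = px + noise[k]
        w = 1.0 if weights is None else weights[k]
        obs.append(Observation2D(view_id=cam.cam_id, pixel=px, weight=w))
    return obs


class TestTriangulation:
    def test_noiseless_exact_recovery(self, rng):
        cams = ring(4)
        for _ in range(20):
            x = rng.uniform([-0.5, -0.5, 0.5], [0.5, 0.5, 1.5])
            rec, res = triangulate_weighted(observe(cams, x), cams)
            assert np.linalg.norm(rec - x) < 1e-6
            assert res < 1e-12

    def test_duplicate_view_equals_double_weight(self, rng):
        cams = ring(3)
        x = np.array([0.2, -0.1, 1.0])
        noise = rng.normal(0, 2.0, size=(3, 2))
        base = observe(cams, x, weights=[0.5, 0.5, 0.5], noise=noise)
        doubled = [
            Observation2D(base[0].view_id, base[0].pixel, 1.0),
            base[1],
            base[2],
        ]
        duplicated = [base[0]] + base
        x_dup, _ = triangulate_weighted(duplicated, cams)
        x_dbl, _ = triangulate_weighted(doubled, cams)
        assert np.allclose(x_dup, x_dbl, atol=1e-9)

    def test_underdetermined(self):
        cams = ring(4)
        obs = observe(cams, np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="underdetermined"):
            triangulate_weighted(obs[:1], cams)

    def test_equal_weights_match_unweighted_dlt_refined_oracle(self, rng):
        cams = ring(5)
        x = np.array([0.1, 0.3, 1.2])
        noise = rng.normal(0, 1.0, size=(5, 2))
        obs = observe(cams, x, noise=noise)
        rec, _ = triangulate_weighted(obs, cams)

        # independent oracle: scipy least-squares on the reprojection error
        from scipy.optimize import least_squares

        pixels = np.array([o.pixel for o in obs])

        def resid(X):
            return np.concatenate(
                [project(c, X) - p for c, p in zip(cams, pixels)]
            )

        sol = least_squares(resid, x0=np.array([0, 0, 1.0]), xtol=1e-15)
        assert np.linalg.norm(rec - sol.x) < 1e-8

    def test_rigid_transform_equivariance(self, rng):
        cams = ring(4)
        x = np.array([0.15, -0.2, 1.1])
        obs = observe(cams, x)
        rot = Rotation.random(random_state=7).as_matrix()
        shift = np.array([1.0, -2.0, 0.5])
        moved_cams = [
            CameraModel(K=c.K, R=c.R @ rot.T, C=rot @ c.C + shift,
                        cam_id=c.cam_id)
            for c in cams
        ]
        rec, _ = triangulate_weighted(obs, moved_cams)
        assert np.allclose(rec, rot @ x + shift, atol=1e-8)


class TestReconstructSequence:
    def _make_obs(self, cams, track, noise_rng=None, sd=0.0):
        frames = []
        for t in range(len(track)):
            per_joint = {}
            for j in range(track.shape[1]):
                noise = (
                    noise_rng.normal(0, sd, size=(len(cams), 2))
                    if noise_rng is not None
                    else None
                )
                per_joint[j] = observe(cams, track[t, j], noise=noise)
            frames.append(per_joint)
        return frames

    def test_zero_lambda_reduces_to_triangulation(self, rng):
        cams = ring(4)
        track = rng.uniform([-0.3, -0.3, 0.6], [0.3, 0.3, 1.4], size=(5, 3, 3))
        frames = self._make_obs(cams, track, noise_rng=rng, sd=1.0)
        seq = reconstruct_sequence(frames, cams, ReconstructionConfig())
        for t in range(5):
            for j in range(3):
                direct, _ = triangulate_weighted(frames[t][j], cams)
                assert np.allclose(seq.positions[t, j], direct, atol=1e-12)

    def test_ground_truth_is_optimal_on_noiseless_data(self, rng):
        cams = ring(4)
        track = rng.uniform([-0.3, -0.3, 0.6], [0.3, 0.3, 1.4], size=(4, 2, 3))
        frames = self._make_obs(cams, track)
        cfg = ReconstructionConfig(lambda_smooth=10.0)
        cams_d = {c.cam_id: c for c in cams}
        at_truth = reconstruction_objective(track, frames, cams_d, cfg)
        perturbed = track + rng.normal(0, 0.01, track.shape)
        at_perturbed = reconstruction_objective(perturbed, frames, cams_d, cfg)
        assert at_truth <= at_perturbed

    def test_smoothing_reduces_jitter(self, rng):
        cams = ring(4)
        base = np.array([0.0, 0.0, 1.0])
        track = base + np.zeros((8, 2, 3))
        track[:, 1, 0] += np.linspace(0, 0.2, 8)
        frames = self._make_obs(cams, track, noise_rng=rng, sd=2.0)
        rec0 = reconstruct_sequence(frames, cams, ReconstructionConfig())
        rec1 = reconstruct_sequence(
            frames, cams,
            ReconstructionConfig(lambda_smooth=1e4, max_iterations=5),
        )

        def jitter(seq):
            return np.mean(
                np.linalg.norm(np.diff(seq.positions, axis=0), axis=2)
            )

        assert jitter(rec1) < jitter(rec0)
        # data fidelity never degrades beyond the lambda-weighted slack
        cams_d = {c.cam_id: c for c in cams}
        cfg0 = ReconstructionConfig()
        e0 = reconstruction_objective(rec0.positions, frames, cams_d, cfg0)
        e1 = reconstruction_objective(rec1.positions, frames, cams_d, cfg0)
        smooth0 = float(np.sum(np.diff(rec0.positions, axis=0) ** 2))
        smooth1 = float(np.sum(np.diff(rec1.positions, axis=0) ** 2))
        assert e1 <= e0 + 1e4 * (smooth0 - smooth1) + 1e-9
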