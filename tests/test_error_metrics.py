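"""Angular deviations, trajectory error, coordination, stability, rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from taijikit.error_metrics import (
    CategoryThresholds,
    StabilityConfig,
    TrajectoryErrorConfig,
    classify_errors,
    coordination_index,
    joint_angle_deviations,
    severity_grade,
    stability_metric,
    trajectory_error,
)
from taijikit.skeleton import SkeletonSequence, support_polygon
from taijikit.synth import ErrorInjection, inject_error
from tests.conftest import make_sequence


class TestSeverityGrade:
    @pytest.mark.parametrize(
        "deviation,expected",
        [
            (4.9, "within_standard"),
            (5.0, "within_standard"),
            (10.0, "minor"),
            (15.0, "moderate"),
            (15.1, "severe"),
            (45.0, "severe"),
        ],
    )
    def test_rubric_bands(self, deviation, expected):
        assert severity_grade(deviation) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            severity_grade(-0.1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(0, 60), st.floats(0, 60))
    def test_monotone(self, a, b):
        order = ["within_standard", "minor", "moderate", "severe"]
        lo, hi = sorted([a, b])
        assert order.index(severity_grade(lo)) <= order.index(
            severity_grade(hi)
        )


class TestTrajectoryError:
    def test_identical_zero(self, rng):
        p = rng.normal(size=(20, 3))
        assert trajectory_error(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_closed_form(self, rng):
        p = rng.normal(size=(15, 3))
        offset = np.array([0.3, -0.4, 0.0])  # |offset| = 0.5
        shifted = p + offset
        # identical velocities: the velocity term contributes nothing
        e = trajectory_error(shifted, p, TrajectoryErrorConfig(alpha_vel=2.0),
                            performed_vel=np.gradient(p, axis=0),
                            reference_vel=np.gradient(p, axis=0))
        assert e == pytest.approx(0.5, abs=1e-12)

    def test_per_frame_oracle(self, rng):
        p = rng.normal(size=(12, 3))
        r = rng.normal(size=(12, 3))
        vp = np.gradient(p, axis=0)
        vr = np.gradient(r, axis=0)
        alpha = 0.7
        oracle = np.mean(
            [
                np.sqrt(
                    np.sum((p[t] - r[t]) ** 2)
                    + alpha * np.sum((vp[t] - vr[t]) ** 2)
                )
                for t in range(12)
            ]
        )
        got = trajectory_error(p, r, TrajectoryErrorConfig(alpha_vel=alpha),
                               performed_vel=vp, reference_vel=vr)
        assert got == pytest.approx(oracle, abs=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            trajectory_error(np.zeros((5, 3)), np.zeros((6, 3)))


class TestCoordination:
    def test_identical_signals_one(self, rng):
        xs = [rng.normal(size=100) for _ in range(3)]
        assert coordination_index(xs, xs) == pytest.approx(1.0, abs=1e-12)

    def test_pure_delay_recovered_within_lag_range(self, rng):
        x = rng.normal(size=200)
        y = np.roll(x, 5)
        c = coordination_index([x[10:-10]], [y[10:-10]])
        assert c > 0.99

    def test_independent_noise_low(self):
        r = np.random.default_rng(77)
        xs = [r.normal(size=200) for _ in range(4)]
        ys = [r.normal(size=200) for _ in range(4)]
        assert abs(coordination_index(xs, ys)) < 0.3

    def test_zero_variance_pair_excluded(self, rng):
        x = rng.normal(size=50)
        with pytest.warns(UserWarning, match="zero variance"):
            c = coordination_index([x, np.zeros(50)], [x, np.ones(50)])
        assert c == pytest.approx(1.0, abs=1e-12)


class TestStability:
    @pytest.fixture
    def square(self):
        return support_polygon(
            np.array([[-0.2, -0.2], [0.2, -0.2], [0.2, 0.2], [-0.2, 0.2]])
        )

    def test_stationary_inside_is_one(self, square):
        com = np.tile([0.0, 0.0, 0.9], (30, 1))
        s = stability_metric(com, com, square, StabilityConfig())
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_reference_variance_closed_form(self, square):
        cfg = StabilityConfig(w1=0.6, w2=0.4, sigma_ref=0.05)
        # two-point static trace with horizontal sway variance sigma_ref^2
        com = np.zeros((2, 3))
        com[0, 0] = -cfg.sigma_ref
        com[1, 0] = cfg.sigma_ref
        s = stability_metric(com, np.tile([0, 0, 0.9], (2, 1)), square, cfg)
        assert s == pytest.approx(0.6 * np.exp(-1.0) + 0.4, abs=1e-12)

    def test_formula_oracle(self, rng, square):
        cfg = StabilityConfig(w1=0.3, w2=0.7, sigma_ref=0.08, d_threshold=0.15)
        cs = rng.normal(0, 0.05, size=(40, 3))
        cd = rng.normal(0, 0.3, size=(40, 3))
        xy = cs[:, :2]
        var = np.mean(np.sum((xy - xy.mean(0)) ** 2, axis=1))
        from taijikit.skeleton import point_to_polygon_distance

        dmax = max(
            max(0.0, point_to_polygon_distance(p, square)) for p in cd[:, :2]
        )
        oracle = 0.3 * np.exp(-var / cfg.sigma_ref**2) + 0.7 * np.exp(
            -dmax / cfg.d_threshold
        )
        got = stability_metric(cs, cd, square, cfg)
        assert got == pytest.approx(oracle, abs=1e-12)


class TestJointAngleDeviations:
    def test_self_comparison_zero(self, reference_motion):
        sub = reference_motion.slice_frames(0, 10)
        dev = joint_angle_deviations(sub, sub)
        finite = dev[np.isfinite(dev)]
        assert finite.size > 0
        assert np.abs(finite).max() < 1e-7  # arccos precision floor

    def test_elbow_flexion_difference(self):
        """A planar arm flexed 90 deg vs 60 deg shows exactly 30 deg at the
        elbow, by a rotation-matrix oracle on the constructed chain."""

        def arm(flex_deg):
            # torso - shoulder - elbow - wrist chain in the x-y plane,
            # plus an out-of-plane torso parent bone for frame definition
            flex = np.deg2rad(flex_deg)
            torso = np.array([0.0, 0.0, 0.5])
            shoulder = np.array([0.0, 0.0, 1.0])
            elbow = shoulder + np.array([0.3, 0.0, 0.0])
            forearm_dir = Rotation.from_euler("z", flex).apply([1.0, 0, 0])
            wrist = elbow + 0.25 * forearm_dir
            pos = np.stack([torso, shoulder, elbow, wrist])[None]
            names = ("torso", "shoulder", "elbow", "wrist")
            edges = ((0, 1), (1, 2), (2, 3))
            return SkeletonSequence(pos, np.ones((1, 4)), 30.0, names, edges)

        dev = joint_angle_deviations(arm(90), arm(60))
        elbow_idx = 2
        assert dev[0, elbow_idx] == pytest.approx(np.pi / 6, abs=1e-7)

    def test_global_rigid_rotation_invariance(self, reference_motion):
        sub = reference_motion.slice_frames(0, 8)
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True)
        moved = sub.with_positions(rot.apply(sub.positions.reshape(-1, 3))
                                   .reshape(sub.positions.shape))
        dev = joint_angle_deviations(moved, sub)
        finite = dev[np.isfinite(dev)]
        assert np.abs(finite).max() < 1e-7

    def test_layout_mismatch_rejected(self, reference_motion, rng):
        other = make_sequence(rng.normal(size=(5, 4, 3)))
        with pytest.raises(ValueError, match="layout"):
            joint_angle_deviations(reference_motion, other)


class TestClassifyErrors:
    def test_clean_replay_empty(self, reference_motion):
        assert classify_errors(reference_motion, reference_motion) == []

    def test_spine_lean_severe(self, reference_motion):
        pert, _ = inject_error(
            reference_motion,
            ErrorInjection(category="spine_alignment", magnitude=20.0),
        )
        reports = classify_errors(pert, reference_motion)
        assert [r.category for r in reports] == ["spine_alignment"]
        assert reports[0].severity == "severe"
        assert reports[0].magnitude == pytest.approx(20.0, abs=2.0)

    def test_knee_past_toe_detected(self, reference_motion):
        pert, _ = inject_error(
            reference_motion,
            ErrorInjection(category="knee_position", magnitude=0.08),
        )
        reports = classify_errors(pert, reference_motion)
        assert [r.category for r in reports] == ["knee_position"]

    def test_reports_sorted_by_significance(self, reference_motion):
        pert, _ = inject_error(
            reference_motion,
            ErrorInjection(category="spine_alignment", magnitude=8.0),
        )
        pert, _ = inject_error(
            pert, ErrorInjection(category="shoulder_tension", magnitude=0.09)
        )
        reports = classify_errors(pert, reference_motion)
        cats = [r.category for r in reports]
        assert set(cats) == {"spine_alignment", "shoulder_tension"}
        thr = CategoryThresholds()
        normalized = [r.magnitude / thr.get(r.category) for r in reports]
        assert normalized == sorted(normalized, reverse=True)
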