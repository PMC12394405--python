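"""Motion energy, boundary detection, DTW alignment and segmentation."""

import numpy as np
import pytest

from taijikit.segmentation import (
    BoundaryConfig,
    EnergyProfile,
    Template,
    boundary_score,
    configuration_similarity,
    detect_keyframes,
    dtw_align,
    motion_energy,
    postural_stability,
    segment_sequence,
)
from taijikit.skeleton import central_velocity
from taijikit.synth import (
    MotionSpec,
    UnitSpec,
    generate_motion,
    random_unit_spec,
    unit_template,
)
from tests.conftest import make_sequence


class TestMotionEnergy:
    def test_stationary_is_zero(self):
        seq = make_sequence(np.ones((10, 4, 3)))
        e = motion_energy(central_velocity(seq), np.ones(4))
        assert np.allclose(e.values, 0.0)

    def test_single_moving_joint_speed_squared(self):
        pos = np.zeros((10, 3, 3))
        pos[:, 1, 0] = 2.0 * np.arange(10)  # speed 2 m/s at fps 1
        seq = make_sequence(pos, fps=1.0)
        e = motion_energy(central_velocity(seq), np.ones(3))
        assert np.allclose(e.values, 4.0)

    def test_double_loop_oracle(self, rng):
        pos = rng.normal(size=(12, 5, 3))
        seq = make_sequence(pos, fps=25.0)
        w = rng.uniform(0, 2, size=5)
        deriv = central_velocity(seq)
        e = motion_energy(deriv, w)
        oracle = np.zeros(12)
        for t in range(12):
            for j in range(5):
                oracle[t] += w[j] * np.dot(deriv.velocity[t, j], deriv.velocity[t, j])
        assert np.allclose(e.values, oracle, rtol=1e-12, atol=1e-12)

    def test_negative_weight_rejected(self, rng):
        seq = make_sequence(rng.normal(size=(5, 2, 3)))
        with pytest.raises(ValueError, match="nonnegative"):
            motion_energy(central_velocity(seq), np.array([1.0, -0.1]))


class TestBoundaryScore:
    def test_derivative_term_zero_for_constant_energy(self):
        e = EnergyProfile(values=np.full(20, 3.0), weights=np.ones(2))
        cfg = BoundaryConfig(alpha=1.0, beta=0.0, gamma=0.0)
        b = boundary_score(e, np.zeros(20), np.zeros(20), cfg)
        assert np.allclose(b, 0.0)

    def test_similarity_term_static_pose(self):
        seq = make_sequence(np.tile(np.arange(6.0).reshape(2, 3), (15, 1, 1)))
        s = configuration_similarity(seq, window=5)
        assert np.allclose(s, 1.0)
        e = EnergyProfile(values=np.zeros(15), weights=np.ones(2))
        cfg = BoundaryConfig(alpha=0.0, beta=1.0, gamma=0.0)
        assert np.allclose(boundary_score(e, s, np.zeros(15), cfg), 1.0)

    def test_extrema_colocate_with_stillness_gap(self, rng):
        """Two movement phases around a constructed stillness gap: the
        boundary score magnitude peaks near the gap edges."""
        spec = MotionSpec(
            (random_unit_spec(rng, 60, unit_id="a"),
             random_unit_spec(rng, 60, unit_id="b")),
            stillness_gap=21, seed=9,
        )
        seq, truth = generate_motion(spec)
        deriv = central_velocity(seq)
        e = motion_energy(deriv, np.ones(32))
        s = configuration_similarity(seq, window=15)
        p = postural_stability(seq)
        cfg = BoundaryConfig(alpha=1.0, beta=0.0, gamma=0.0)
        b = boundary_score(e, s, p, cfg, dt=seq.dt)
        gap_center = truth[0].end
        # |dE/dt| vanishes inside the gap and is large at its flanks
        assert np.abs(b[gap_center - 2:gap_center + 3]).max() < 1e-6
        assert np.abs(b[55:65]).max() > 10 * np.abs(b[gap_center]).max()

    def test_length_mismatch_rejected(self):
        e = EnergyProfile(values=np.zeros(5), weights=np.ones(1))
        with pytest.raises(ValueError, match="mismatch"):
            boundary_score(e, np.zeros(4), np.zeros(5), BoundaryConfig())


class TestKeyframes:
    def test_monotone_energy_no_interior_keyframes(self):
        e = EnergyProfile(values=np.linspace(0, 5, 100) ** 2,
                          weights=np.ones(1))
        kf = detect_keyframes(e, BoundaryConfig(stillness_percentile=100.0))
        assert all(k < 10 for k in kf)  # nothing beyond the initial low end

    def test_abs_sine_minima_at_period_multiples(self):
        t = np.arange(200)
        e = EnergyProfile(values=np.abs(np.sin(np.pi * t / 40)),
                          weights=np.ones(1))
        cfg = BoundaryConfig(window_min=8, window_max=16,
                             min_peak_separation=10,
                             stillness_percentile=30.0)
        kf = detect_keyframes(e, cfg)
        targets = [40, 80, 120, 160]
        for target in targets:
            assert any(abs(k - target) <= 1 for k in kf), (target, kf)

    def test_flat_profile_keeps_first_plateau_frame(self):
        e = EnergyProfile(values=np.zeros(50), weights=np.ones(1))
        kf = detect_keyframes(e, BoundaryConfig())
        assert list(kf) == [0]


class TestDTW:
    def test_identical_zero_distance_diagonal_path(self, rng):
        seq = make_sequence(rng.normal(size=(30, 4, 3)))
        d, path = dtw_align(seq, Template("t", seq))
        assert d == 0.0
        assert path == [(i, i) for i in range(30)]

    def test_frame_doubling_time_scale_invariance(self, rng):
        seq = make_sequence(rng.normal(size=(25, 4, 3)))
        doubled = make_sequence(np.repeat(seq.positions, 2, axis=0))
        d, _ = dtw_align(doubled, Template("t", seq))
        assert d == 0.0

    def test_matches_exhaustive_dp_oracle(self, rng):
        for _ in range(10):
            a = make_sequence(rng.normal(size=(20, 3, 3)))
            b = make_sequence(rng.normal(size=(25, 3, 3)))
            d, path = dtw_align(a, Template("t", b), band_fraction=None)
            oracle = _naive_dtw(a, b)
            assert abs(d - oracle) < 1e-10
            # path validity: monotone, contiguous, endpoints matched
            assert path[0] == (0, 0) and path[-1] == (19, 24)
            for (i0, j0), (i1, j1) in zip(path, path[1:]):
                assert (i1 - i0, j1 - j0) in {(0, 1), (1, 0), (1, 1)}

    def test_empty_rejected(self, rng):
        seq = make_sequence(rng.normal(size=(5, 2, 3)))
        with pytest.raises(ValueError):
            Template("t", make_sequence(np.empty((0, 2, 3))))
        del seq


def _naive_dtw(a_seq, b_seq):
    a = (a_seq.positions - a_seq.positions[:, :1]).reshape(a_seq.n_frames, -1)
    b = (b_seq.positions - b_seq.positions[:, :1]).reshape(b_seq.n_frames, -1)
    n, m = len(a), len(b)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = d[i - 1, j - 1] + min(
                acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1]
            )
    i, j, length = n, m, 0
    while i > 0 and j > 0:
        length += 1
        _, i, j = min(
            [(acc[i - 1, j - 1], i - 1, j - 1), (acc[i - 1, j], i - 1, j),
             (acc[i, j - 1], i, j - 1)],
            key=lambda t: t[0],
        )
    return acc[n, m] / length


class TestSegmentSequence:
    def _concat(self, rng, n_units=3, gap=15, noise=0.0, seed=11):
        specs = tuple(
            random_unit_spec(rng, 60, unit_id=f"u{i}") for i in range(n_units)
        )
        spec = MotionSpec(specs, stillness_gap=gap, noise_sd=noise, seed=seed)
        seq, truth = generate_motion(spec)
        templates = [unit_template(u) for u in specs]
        return seq, truth, templates

    def test_three_templates_recovered_in_order(self, rng):
        seq, truth, templates = self._concat(rng)
        segs = segment_sequence(seq, templates, BoundaryConfig())
        valid = [s for s in segs if s.valid]
        assert len(valid) == 3
        assert [s.label for s in valid] == ["u0", "u1", "u2"]
        for s, t in zip(valid, truth):
            assert abs(s.start - t.start) <= 3 and abs(s.end - t.end) <= 3

    def test_segments_cover_sequence_disjointly(self, rng):
        seq, _, templates = self._concat(rng, n_units=4, seed=13)
        segs = segment_sequence(seq, templates, BoundaryConfig())
        assert segs[0].start == 0 and segs[-1].end == seq.n_frames
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_pure_stillness_single_invalid_segment(self):
        spec = MotionSpec(
            (UnitSpec(duration=120, channels={}, unit_id="rest"),), seed=1
        )
        seq, _ = generate_motion(spec)
        segs = segment_sequence(seq, [], BoundaryConfig())
        assert len(segs) == 1 and not segs[0].valid

    def test_short_pause_does_not_split_segment(self, rng):
        """A 5-frame mid-movement freeze is a momentary pause, not a
        boundary: false-positive suppression."""
        spec = MotionSpec(
            (random_unit_spec(rng, 80, unit_id="u"),), seed=17
        )
        seq, _ = generate_motion(spec)
        pos = seq.positions.copy()
        pos[40:45] = pos[40]  # inject the jitter pause
        paused = seq.with_positions(pos)
        tpl = Template("u", seq)
        segs = segment_sequence(paused, [tpl], BoundaryConfig())
        valid = [s for s in segs if s.valid]
        assert len(valid) == 1
        assert valid[0].label == "u"

    def test_short_sequence_single_unknown_segment(self, rng):
        seq = make_sequence(rng.normal(size=(10, 4, 3)))
        with pytest.warns(UserWarning, match="shorter than window_min"):
            segs = segment_sequence(seq, [], BoundaryConfig())
        assert len(segs) == 1 and segs[0].label == "unknown"
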