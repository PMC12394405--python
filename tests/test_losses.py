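"""Composite loss components, expert-knowledge constraints, distillation."""

import numpy as np
import pytest

from taijikit.autodiff import Tensor
from taijikit.losses import (
    LossWeights,
    cross_entropy,
    expert_loss,
    kd_loss,
    pose_similarity,
    smoothness_loss,
    total_loss,
)


def default_expert_inputs(rng=None, T=20):
    rng = rng or np.random.default_rng(0)
    return dict(
        foot_weights=rng.uniform(0.2, 1.0, size=(T, 2)),
        joint_angles=rng.normal(size=(T, 3)),
        spine_angles=rng.uniform(1.0, 2.0, size=T),
        shoulder_angles=rng.normal(size=(T, 2)),
        force_pairs=rng.uniform(0.1, 1.0, size=(8, 2)),
    )


class TestPoseSimilarity:
    def test_identical_is_one(self, rng):
        p = rng.normal(size=(5, 3))
        assert pose_similarity(p, p) == pytest.approx(1.0)

    def test_single_joint_closed_form(self):
        ref = np.zeros((1, 3))
        moved = np.array([[0.7, 0.0, 0.0]])
        assert pose_similarity(moved, ref) == pytest.approx(np.exp(-0.7))

    def test_strictly_decreasing_in_displacement(self):
        ref = np.zeros((2, 3))
        s1 = pose_similarity(ref + [0.1, 0, 0], ref)
        s2 = pose_similarity(ref + [0.2, 0, 0], ref)
        assert s2 < s1 < 1.0

    def test_exponent_oracle(self, rng):
        p = rng.normal(size=(6, 3))
        r = rng.normal(size=(6, 3))
        w = rng.uniform(0.5, 1.5, size=6)
        oracle = np.exp(-np.mean(w * np.linalg.norm(p - r, axis=1)))
        assert pose_similarity(p, r, joint_weights=w) == pytest.approx(
            oracle, abs=1e-10
        )

    def test_mismatched_joints_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pose_similarity(np.zeros((3, 3)), np.zeros((4, 3)))


class TestExpertLoss:
    def test_balance_zero_when_symmetric(self):
        inputs = default_expert_inputs()
        inputs["foot_weights"] = np.full((20, 2), 0.5)
        _, parts = expert_loss(**inputs, cfg=LossWeights(w_target=0.0))
        assert parts["balance"] == pytest.approx(0.0, abs=1e-12)

    def test_flow_zero_for_constant_angular_velocity(self):
        inputs = default_expert_inputs()
        t = np.arange(20.0)
        inputs["joint_angles"] = np.stack([0.3 * t, -0.1 * t, 2 * t], axis=1)
        _, parts = expert_loss(**inputs, cfg=LossWeights())
        assert parts["flow"] == pytest.approx(0.0, abs=1e-12)

    def test_alignment_zero_at_vertical_spine_and_reference_shoulders(self):
        inputs = default_expert_inputs()
        inputs["spine_angles"] = np.full(20, np.pi / 2)
        inputs["shoulder_angles"] = np.full((20, 2), 0.3)
        _, parts = expert_loss(**inputs, cfg=LossWeights(theta_reference=0.3))
        assert parts["alignment"] == pytest.approx(0.0, abs=1e-12)

    def test_substantial_boundary_cases(self):
        inputs = default_expert_inputs()
        inputs["force_pairs"] = np.array([[1.0, 0.0]])  # fully differentiated
        _, parts = expert_loss(**inputs, cfg=LossWeights())
        assert parts["substantial"] == pytest.approx(0.0, abs=1e-12)
        inputs["force_pairs"] = np.array([[0.5, 0.5]])  # undifferentiated
        _, parts = expert_loss(**inputs, cfg=LossWeights())
        assert parts["substantial"] == pytest.approx(1.0, abs=1e-12)

    def test_weighted_sum_reproduces_total(self, rng):
        inputs = default_expert_inputs(rng)
        cfg = LossWeights()
        tot, parts = expert_loss(**inputs, cfg=cfg)
        expected = (
            0.3 * parts["balance"] + 0.25 * parts["flow"]
            + 0.25 * parts["alignment"] + 0.2 * parts["substantial"]
        )
        assert float(tot.data) == pytest.approx(expected, abs=1e-12)

    def test_zero_sum_frames_dropped_with_warning(self):
        inputs = default_expert_inputs()
        inputs["foot_weights"][3] = 0.0
        with pytest.warns(UserWarning, match="zero-sum foot"):
            tot, _ = expert_loss(**inputs, cfg=LossWeights())
        assert np.isfinite(float(tot.data))

    def test_finite_difference_gradients(self, rng):
        """Analytic gradients through every expert component match central
        finite differences."""
        cfg = LossWeights(w_target=0.2, theta_reference=0.1)
        arrays = default_expert_inputs(rng, T=8)

        tensors = {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}
        tot, _ = expert_loss(**tensors, cfg=cfg, dt=0.5)
        tot.backward()

        eps = 1e-6
        for name, base in arrays.items():
            grad = tensors[name].grad
            flat = base.ravel()
            for idx in np.random.default_rng(0).choice(
                flat.size, size=min(6, flat.size), replace=False
            ):
                bumped = dict(arrays)
                plus = base.copy().ravel()
                plus[idx] += eps
                bumped[name] = plus.reshape(base.shape)
                lp, _ = expert_loss(**bumped, cfg=cfg, dt=0.5)
                minus = base.copy().ravel()
                minus[idx] -= eps
                bumped[name] = minus.reshape(base.shape)
                lm, _ = expert_loss(**bumped, cfg=cfg, dt=0.5)
                fd = (float(lp.data) - float(lm.data)) / (2 * eps)
                assert grad.ravel()[idx] == pytest.approx(fd, abs=1e-4), name


class TestTotalLoss:
    def test_zero_at_optimum(self):
        logits = Tensor(np.array([[50.0, 0.0, 0.0, 0.0]]))
        hidden = Tensor(np.zeros((1, 6, 8)))
        tot, parts = total_loss(
            logits, np.array([0]), hidden, LossWeights(),
            style_similarities=np.array([1.0]),
        )
        assert float(tot.data) == pytest.approx(0.0, abs=1e-12)

    def test_gamma_zero_ignores_expert_components(self, rng):
        logits = Tensor(rng.normal(size=(3, 4)))
        targets = np.array([0, 1, 2])
        inputs = default_expert_inputs(rng)
        expert = expert_loss(**inputs, cfg=LossWeights())
        cfg0 = LossWeights(gamma_expert=0.0)
        t_without, _ = total_loss(logits, targets, None, cfg0)
        t_with, _ = total_loss(logits, targets, None, cfg0,
                               expert_terms=expert)
        assert float(t_without.data) == float(t_with.data)

    def test_sum_of_parts_oracle(self, rng):
        logits = Tensor(rng.normal(size=(4, 4)))
        targets = rng.integers(0, 4, size=4)
        hidden = Tensor(rng.normal(size=(4, 6, 8)))
        sims = rng.uniform(0, 1, size=4)
        inputs = default_expert_inputs(rng)
        cfg = LossWeights(alpha_smooth=0.3, beta_style=0.7, gamma_expert=0.5)
        expert = expert_loss(**inputs, cfg=cfg)
        tot, parts = total_loss(logits, targets, hidden, cfg,
                                style_similarities=sims, expert_terms=expert)
        oracle = (
            float(cross_entropy(Tensor(logits.data), targets).data)
            + 0.3 * float(smoothness_loss(Tensor(hidden.data)).data)
            + 0.7 * float(np.mean(1 - sims))
            + 0.5 * float(expert[0].data)
        )
        assert float(tot.data) == pytest.approx(oracle, abs=1e-8)
        recombined = (
            parts["acc"] + 0.3 * parts["smooth"] + 0.7 * parts["style"]
            + 0.5 * parts["expert"]
        )
        assert recombined == pytest.approx(float(tot.data), abs=1e-8)


class TestKDLoss:
    def test_identical_logits_zero(self, rng):
        z = rng.normal(size=(3, 4))
        assert float(kd_loss(Tensor(z), z, temperature=2.0).data) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_high_temperature_softening_limit(self, rng):
        """As tau grows the softened distributions converge (raw KL -> 0);
        the tau^2 factor is calibrated so the scaled loss approaches a
        finite constant instead of vanishing."""
        s = rng.normal(size=(1, 4))
        t = rng.normal(size=(1, 4))
        v1 = float(kd_loss(Tensor(s), t, temperature=1e3).data)
        v2 = float(kd_loss(Tensor(s), t, temperature=2e3).data)
        assert v1 / 1e3**2 < 1e-6          # raw KL vanishes
        assert v2 == pytest.approx(v1, rel=1e-2)  # scaled loss stabilizes

    def test_hand_computed_kl_oracle(self):
        s = np.array([[1.0, 0.0, -1.0, 0.5]])
        t = np.array([[0.5, 0.5, 0.0, -0.5]])
        tau = 2.0
        ps = np.exp(s / tau) / np.exp(s / tau).sum()
        pt = np.exp(t / tau) / np.exp(t / tau).sum()
        oracle = tau**2 * float(np.sum(ps * (np.log(ps) - np.log(pt))))
        assert float(kd_loss(Tensor(s), t, tau).data) == pytest.approx(
            oracle, abs=1e-8
        )

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            kd_loss(Tensor(np.zeros((1, 4))), np.zeros((1, 4)), 0.0)


def test_loss_weights_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        LossWeights(alpha1_balance=0.5)
    with pytest.raises(ValueError, match="kd_temperature"):
        LossWeights(kd_temperature=-1.0)
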