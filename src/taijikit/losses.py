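"""Composite training losses with expert-knowledge constraints.

The total objective is

    L_total = L_acc + alpha L_smooth + beta L_style + gamma L_expert

where L_acc is cross-entropy over the four quality classes, L_smooth the
mean squared frame-to-frame difference of the hidden embedding sequence,
L_style the mean complement of the pose-similarity score against a style
reference, and L_expert a weighted sum of four differentiable rule
constraints encoding traditional movement principles:

    L_expert = a1 L_balance + a2 L_flow + a3 L_alignment + a4 L_substantial

* balance — the normalized left/right foot-weight asymmetry should track a
  target ratio (0 for symmetric stances, 0.4 for a 70/30 bow stance);
* flow — joint-angle trajectories should have small second time
  derivatives (continuous circular transitions);
* alignment — the spine stays vertical and the shoulders at their
  reference angles;
* substantial — weight-bearing ("substantial") and unweighted
  ("insubstantial") limbs should be clearly differentiated.

A temperature-softened knowledge-distillation term transfers ensemble
expert label distributions to the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from taijikit.autodiff import Tensor
from taijikit.skeleton import UnitQuaternion, quaternion_angle

__all__ = [
    "LossWeights",
    "pose_similarity",
    "expert_loss",
    "total_loss",
    "kd_loss",
    "cross_entropy",
]


@dataclass(frozen=True)
class LossWeights:
    """Mixing weights of the composite loss."""

    alpha_smooth: float = 0.1
    beta_style: float = 0.1
    gamma_expert: float = 0.1
    # expert-rule weights, fixed from expert consultation; must sum to 1
    alpha1_balance: float = 0.3
    alpha2_flow: float = 0.25
    alpha3_alignment: float = 0.25
    alpha4_substantial: float = 0.2
    w_target: float = 0.0
    theta_reference: float = 0.0
    kd_temperature: float = 2.0

    def __post_init__(self) -> None:
        s = (
            self.alpha1_balance + self.alpha2_flow
            + self.alpha3_alignment + self.alpha4_substantial
        )
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"expert weights must sum to 1, got {s}")
        if self.kd_temperature <= 0:
            raise ValueError("kd_temperature must be positive")
        if not 0.0 <= self.w_target <= 1.0:
            raise ValueError("w_target must lie in [0, 1]")


def _lift(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def pose_similarity(
    performed: np.ndarray,
    reference: np.ndarray,
    joint_weights: np.ndarray | None = None,
    lambda_ang: float = 0.0,
    quaternions_performed: list[UnitQuaternion] | None = None,
    quaternions_reference: list[UnitQuaternion] | None = None,
) -> float:
    """Pose similarity S = exp(-(1/N) sum_i w_i (d_pos + lambda d_ang)).

    ``performed`` and ``reference`` are (J, 3) single poses; d_pos is the
    Euclidean distance in meters and d_ang the quaternion geodesic angle in
    radians when joint rotations are supplied.  S is 1 iff the poses are
    identical and strictly decreasing in every deviation.
    """
    p = np.asarray(performed, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"joint count mismatch: {p.shape} vs {r.shape}")
    n = p.shape[0]
    w = np.ones(n) if joint_weights is None else np.asarray(joint_weights, float)
    d_pos = np.linalg.norm(p - r, axis=1)
    d_ang = np.zeros(n)
    if lambda_ang != 0.0 and quaternions_performed is not None:
        d_ang = np.array(
            [
                quaternion_angle(qr, qp)
                for qr, qp in zip(quaternions_reference, quaternions_performed)
            ]
        )
    return float(np.exp(-np.mean(w * (d_pos + lambda_ang * d_ang))))


def expert_loss(
    foot_weights: np.ndarray | Tensor,
    joint_angles: np.ndarray | Tensor,
    spine_angles: np.ndarray | Tensor,
    shoulder_angles: np.ndarray | Tensor,
    force_pairs: np.ndarray | Tensor,
    cfg: LossWeights,
    dt: float = 1.0,
) -> tuple[Tensor, dict[str, float]]:
    """Expert-knowledge loss with component breakdown.

    Parameters
    ----------
    foot_weights : (T, 2)
        Per-frame left/right foot weights, nonnegative with positive sum.
        Frames with zero total weight are rejected (dropped with a warning).
    joint_angles : (T, A)
        Joint-angle trajectories in radians for the flow term.
    spine_angles : (T,)
        Spine inclination angle per frame (pi/2 = vertical).
    shoulder_angles : (T, 2)
        Left/right shoulder angles, compared against ``theta_reference``.
    force_pairs : (N, 2)
        Substantial/insubstantial force magnitudes per step.

    Returns the scalar loss tensor (differentiable through every input
    supplied as a :class:`~taijikit.autodiff.Tensor`) and a float
    breakdown dict.
    """
    fw = _lift(foot_weights)
    totals = fw.data.sum(axis=1)
    good = totals > 0
    if not np.all(good):
        warnings.warn(
            f"dropping {np.count_nonzero(~good)} frame(s) with zero-sum foot "
            "weights from L_balance",
            stacklevel=2,
        )
        fw = fw[np.where(good)[0]]
    if fw.shape[0] == 0:
        raise ValueError("no frames with positive foot-weight sum")
    wl, wr = fw[:, 0], fw[:, 1]
    asym = (wl - wr).abs() / (wl + wr)
    l_balance = ((asym - cfg.w_target) ** 2.0).mean()

    th = _lift(joint_angles)
    if th.shape[0] < 3:
        raise ValueError("flow term needs at least 3 frames of joint angles")
    second = (th[2:] - th[1:-1] * 2.0 + th[:-2]) * (1.0 / dt**2)
    l_flow = second.abs().mean()

    sp = _lift(spine_angles)
    sh = _lift(shoulder_angles)
    l_alignment = ((sp - np.pi / 2.0) ** 2.0).mean() + (
        ((sh - cfg.theta_reference) ** 2.0).sum(axis=1)
    ).mean()

    fp = _lift(force_pairs)
    fs, fi = fp[:, 0], fp[:, 1]
    l_subst = (1.0 - (fs - fi).abs() / (fs + fi)).mean()

    total = (
        cfg.alpha1_balance * l_balance
        + cfg.alpha2_flow * l_flow
        + cfg.alpha3_alignment * l_alignment
        + cfg.alpha4_substantial * l_subst
    )
    breakdown = {
        "balance": float(l_balance.data),
        "flow": float(l_flow.data),
        "alignment": float(l_alignment.data),
        "substantial": float(l_subst.data),
    }
    return total, breakdown


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over integer class targets."""
    logp = logits.log_softmax(axis=1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(targets, int)]
    return -picked.mean()


def smoothness_loss(hidden_seq: Tensor) -> Tensor:
    """Mean squared frame-to-frame difference of the embedding sequence."""
    d = hidden_seq[:, 1:, :] - hidden_seq[:, :-1, :]
    return (d ** 2.0).mean()


def total_loss(
    logits: Tensor,
    targets: np.ndarray,
    hidden_seq: Tensor | None,
    cfg: LossWeights,
    style_similarities: np.ndarray | None = None,
    expert_terms: tuple[Tensor, dict] | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """L_total = L_acc + alpha L_smooth + beta L_style + gamma L_expert.

    Components that are not applicable may be omitted (treated as zero).
    Returns the scalar tensor plus a float component breakdown whose
    weighted sum reproduces the total.
    """
    l_acc = cross_entropy(logits, targets)
    parts: dict[str, float] = {"acc": float(l_acc.data)}
    total = l_acc
    if hidden_seq is not None and cfg.alpha_smooth != 0.0:
        l_smooth = smoothness_loss(hidden_seq)
        total = total + cfg.alpha_smooth * l_smooth
        parts["smooth"] = float(l_smooth.data)
    else:
        parts["smooth"] = 0.0
    if style_similarities is not None and cfg.beta_style != 0.0:
        l_style = Tensor(float(np.mean(1.0 - np.asarray(style_similarities))))
        total = total + cfg.beta_style * l_style
        parts["style"] = float(l_style.data)
    else:
        parts["style"] = 0.0
    if expert_terms is not None and cfg.gamma_expert != 0.0:
        l_expert, breakdown = expert_terms
        total = total + cfg.gamma_expert * l_expert
        parts["expert"] = float(l_expert.data)
        parts.update({f"expert_{k}": v for k, v in breakdown.items()})
    else:
        parts["expert"] = 0.0
    parts["total"] = float(total.data)
    return total, parts


def kd_loss(
    student_logits: Tensor | np.ndarray,
    teacher_logits: np.ndarray,
    temperature: float,
) -> Tensor:
    """Knowledge distillation: L_KD = tau^2 KL(p_s^tau || p_t^tau).

    Both logit vectors are softened by the temperature tau before the KL
    divergence; the tau^2 factor keeps gradient magnitudes comparable
    across temperatures.  Zero iff the softened distributions coincide.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = _lift(student_logits)
    t = np.asarray(teacher_logits, dtype=float)
    if s.shape != t.shape:
        raise ValueError("student and teacher logits must have equal shapes")
    tau = float(temperature)
    logp_s = (s * (1.0 / tau)).log_softmax(axis=-1)
    zt = t / tau
    zt = zt - zt.max(axis=-1, keepdims=True)
    p_t_log = zt - np.log(np.exp(zt).sum(axis=-1, keepdims=True))
    p_s = logp_s.exp()
    kl = (p_s * (logp_s - Tensor(p_t_log))).sum(axis=-1).mean()
    return kl * tau**2
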