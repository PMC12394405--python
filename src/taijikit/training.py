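"""Curriculum training loop for the assessment network.

Training proceeds through ordered curriculum stages — static postures
first, then movement transitions, finally full sequences — with the items
of each stage added cumulatively.  Optimization uses Adam (initial
learning rate 0.001) with the learning rate halved when the monitored
loss plateaus.  Optional augmentation applies temporal scaling, spatial
rotation within +-15 degrees, uniform scaling in 0.9-1.1 and Gaussian
noise injection.  All randomness flows through one seeded generator, so a
repeated run is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from taijikit.autodiff import Tensor
from taijikit.losses import LossWeights, smoothness_loss, cross_entropy
from taijikit.network import AssessmentModel

__all__ = ["TrainConfig", "Adam", "train", "TrainHistory"]

STAGES = ("posture", "transition", "sequence")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    lr_decay: float = 0.5
    plateau_patience: int = 10
    plateau_min_delta: float = 1e-4
    epochs_per_stage: tuple[int, ...] = (10, 10, 30)
    batch_size: int = 2
    curriculum_stages: tuple[str, ...] = STAGES
    augment: bool = False
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if len(self.epochs_per_stage) != len(self.curriculum_stages):
            raise ValueError("one epoch budget per curriculum stage required")


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return self.epochs


def _augment_item(x: np.ndarray, rng: np.random.Generator,
                  cfg: TrainConfig) -> np.ndarray:
    """x: (V, 3, T) -> augmented copy (temporal scale, rotate, scale, noise)."""
    V, C, T = x.shape
    out = x
    # temporal scaling: resample to a stretched length, crop/pad back to T
    factor = rng.uniform(0.9, 1.1)
    src = np.clip((np.arange(T) * factor), 0, T - 1)
    i0 = src.astype(int)
    i1 = np.minimum(i0 + 1, T - 1)
    frac = src - i0
    out = out[:, :, i0] * (1 - frac) + out[:, :, i1] * frac
    # spatial rotation about the vertical axis
    ang = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    ca, sa = np.cos(ang), np.sin(ang)
    rot = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    out = np.einsum("ij,vjt->vit", rot, out)
    out = out * rng.uniform(*cfg.scale_range)
    out = out + rng.normal(0.0, cfg.noise_sd, out.shape)
    return out


def train(
    model: AssessmentModel,
    items: np.ndarray,
    labels: np.ndarray,
    stages: list[str],
    cfg: TrainConfig,
    loss_weights: LossWeights | None = None,
    val_items: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> TrainHistory:
    """Train a model through the curriculum; returns the epoch history.

    ``items`` is (N, joints, 3, frames); ``stages[i]`` tags each item with
    its curriculum stage.  Stages run in the configured order and each
    stage trains on all items tagged with it *or an earlier stage*.  The
    learning rate halves whenever the monitored loss (validation loss if a
    validation split is given, else training loss) fails to improve by
    ``plateau_min_delta`` for ``plateau_patience`` epochs.
    """
    lw = loss_weights or LossWeights()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), cfg.lr)
    history = TrainHistory()
    stages_arr = np.asarray(stages)
    labels = np.asarray(labels, int)

    best = np.inf
    stall = 0
    for stage_idx, (stage, n_epochs) in enumerate(
        zip(cfg.curriculum_stages, cfg.epochs_per_stage)
    ):
        allowed = set(cfg.curriculum_stages[: stage_idx + 1])
        mask = np.isin(stages_arr, list(allowed))
        idx_pool = np.where(mask)[0]
        if len(idx_pool) == 0:
            import warnings

            warnings.warn(f"curriculum stage '{stage}' has no items; skipping",
                          stacklevel=2)
            continue
        # epoch-frozen batch-norm statistics: normalize every step with the
        # current population stats (recomputed each epoch) so tiny batches
        # optimize the same function that evaluation sees
        model.calibrate_norm(items[idx_pool])
        model.set_norm_frozen(True)
        for _ in range(n_epochs):
            order = rng.permutation(idx_pool)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                xb = items[batch]
                if cfg.augment:
                    xb = np.stack([_augment_item(x, rng, cfg) for x in xb])
                yb = labels[batch]
                opt.zero_grad()
                logits, _, _, extras = model.forward(xb, train=True)
                loss = cross_entropy(logits, yb)
                comp = {"acc_ce": float(loss.data)}
                if lw.alpha_smooth != 0.0:
                    l_smooth = smoothness_loss(extras["hidden_seq"])
                    loss = loss + lw.alpha_smooth * l_smooth
                    comp["smooth"] = float(l_smooth.data)
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(batch)
                correct += int(
                    (logits.data.argmax(axis=1) == yb).sum()
                )
            epoch_loss /= len(order)
            train_acc = correct / len(order)
            # refresh norm statistics so eval-mode metrics reflect the
            # current parameters rather than lagged running averages
            model.calibrate_norm(items[idx_pool])
            row = {
                "stage": stage,
                "lr": opt.lr,
                "train_loss": epoch_loss,
                "train_acc": train_acc,  # under dropout, during optimization
            }
            train_logits = model.assess(items[idx_pool]).logits
            row["train_acc_eval"] = float(
                (train_logits.argmax(axis=1) == labels[idx_pool]).mean()
            )
            monitored = epoch_loss
            if val_items is not None:
                val_logits = model.assess(val_items).logits
                vl = float(cross_entropy(Tensor(val_logits), val_labels).data)
                vacc = float(
                    (val_logits.argmax(axis=1) == np.asarray(val_labels)).mean()
                )
                row["val_loss"] = vl
                row["val_acc"] = vacc
                monitored = vl
            history.epochs.append(row)
            # plateau-based learning-rate decay
            if monitored < best - cfg.plateau_min_delta:
                best = monitored
                stall = 0
            else:
                stall += 1
                if stall >= cfg.plateau_patience:
                    opt.lr *= cfg.lr_decay
                    stall = 0
    model.set_norm_frozen(False)
    return history
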