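"""Attention-enhanced spatio-temporal graph network for quality assessment.

The backbone stacks ST-GCN blocks — per-partition masked graph convolution

    f_out = sum_k W_k (A_k ⊙ M_k) f_in Θ_k

followed by a temporal convolution (kernel 9) with residual connections —
then a dual-attention stage: spatial attention α_s over joints per frame
and temporal attention α_t over frames, both of the form
softmax(w · tanh(W_v V + W_h H)).  A bidirectional LSTM runs over time per
joint, attention-weighted pooling produces a 512-d quality embedding, and
a two-layer classifier outputs four quality classes (a linear regression
head for continuous scoring shares the embedding).

Default hyperparameters define the full-size architecture: 32 joints x 3
coordinates x 150 frames in; three block groups of 64/128/256 channels
with strides 1/2/2 (150 -> 75 -> 38 frames by ceil division); 8 attention
heads with dropout 0.1; dropout 0.3 after each block; 512 bidirectional
LSTM units (256 per direction); classifier 512 -> 256 -> 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from taijikit.autodiff import Tensor, concatenate, conv1d, no_grad
from taijikit.graph import GraphSpec, build_skeleton_graph

__all__ = ["ModelConfig", "AssessmentModel", "stgcn_spatial", "AssessmentResult"]


@dataclass(frozen=True)
class ModelConfig:
    joints: int = 32
    in_channels: int = 3
    seq_len: int = 150
    # (channels, temporal_kernel, stride) per block
    blocks: tuple[tuple[int, int, int], ...] = (
        (64, 9, 1), (64, 9, 1), (64, 9, 1),
        (128, 9, 2), (128, 9, 1), (128, 9, 1),
        (256, 9, 2), (256, 9, 1), (256, 9, 1), (256, 9, 1),
    )
    attention_heads: int = 8
    attention_dropout: float = 0.1
    lstm_units: int = 512  # total over both directions
    classifier_hidden: int = 256
    n_classes: int = 4
    block_dropout: float = 0.3

    def __post_init__(self) -> None:
        chans = [c for c, _, _ in self.blocks]
        if any(b < a for a, b in zip(chans, chans[1:])):
            raise ValueError("block channel counts must be non-decreasing")
        if any(s < 1 for _, _, s in self.blocks):
            raise ValueError("strides must be >= 1")
        if self.lstm_units % 2 != 0:
            raise ValueError("lstm_units must be even (bidirectional)")


def stgcn_spatial(
    f_in: Tensor | np.ndarray,
    graph: GraphSpec,
    thetas: list[Tensor | np.ndarray],
) -> Tensor:
    """Masked multi-partition graph convolution.

    ``f_in`` is (B, C, T, V); ``thetas[k]`` is the (C, C_out) channel-mixing
    matrix Θ_k of partition k.  Returns
    sum_k (A_k_norm ⊙ M_k) f_in Θ_k, shape (B, C_out, T, V).
    """
    x = f_in if isinstance(f_in, Tensor) else Tensor(f_in)
    if x.ndim != 4 or x.shape[3] != graph.n_joints:
        raise ValueError(
            f"f_in must be (B, C, T, V={graph.n_joints}), got {x.shape}"
        )
    if len(thetas) != graph.k_s:
        raise ValueError("one theta per partition required")
    out = None
    for k in range(graph.k_s):
        a_eff = graph.effective(k)  # (V, V)
        theta = thetas[k] if isinstance(thetas[k], Tensor) else Tensor(thetas[k])
        # aggregate neighbors: out[...,v] = sum_w a_eff[v,w] x[...,w]
        agg = x @ a_eff.transpose((1, 0))
        # mix channels: (B,C,T,V) -> (B,T,V,C) @ (C,O) -> back
        mixed = (agg.transpose((0, 2, 3, 1)) @ theta).transpose((0, 3, 1, 2))
        out = mixed if out is None else out + mixed
    return out


def _same_ceil_pad(t: int, k: int, stride: int) -> tuple[int, int]:
    """Padding so that T_out = ceil(T / stride) with kernel k."""
    t_out = -(-t // stride)
    total = max((t_out - 1) * stride + k - t, 0)
    left = total // 2
    return left, total - left


class _Param:
    """Helper: create an initialized parameter tensor."""

    @staticmethod
    def glorot(rng: np.random.Generator, *shape: int) -> Tensor:
        fan_in, fan_out = shape[-1], shape[0] if len(shape) > 1 else shape[-1]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)

    @staticmethod
    def zeros(*shape: int) -> Tensor:
        return Tensor(np.zeros(shape), requires_grad=True)

    @staticmethod
    def ones(*shape: int) -> Tensor:
        return Tensor(np.ones(shape), requires_grad=True)


class BatchNorm:
    """Batch normalization per channel over (batch, time, joints)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = _Param.ones(channels)
        self.beta = _Param.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        # when frozen, training steps normalize with the stored population
        # statistics instead of per-batch ones (small-batch stability)
        self.freeze_stats = False

    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        # x: (B, C, T, V) or (B, C, T)
        axes = tuple(i for i in range(x.ndim) if i != 1)
        bshape = tuple(-1 if i == 1 else 1 for i in range(x.ndim))
        if train and not self.freeze_stats:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.reshape(-1)
            self.running_var = m * self.running_var + (1 - m) * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean.reshape(bshape))
            var = Tensor(self.running_var.reshape(bshape))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(bshape) + self.beta.reshape(bshape)


class STGCNBlock:
    """Graph convolution + temporal convolution with residual connection."""

    def __init__(
        self,
        rng: np.random.Generator,
        graph: GraphSpec,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        dropout: float,
    ):
        self.graph = graph
        self.stride = stride
        self.kernel = kernel
        self.dropout = dropout
        self.thetas = [_Param.glorot(rng, c_in, c_out) for _ in range(graph.k_s)]
        self.gcn_bias = _Param.zeros(c_out)
        self.bn1 = BatchNorm(c_out)
        self.tconv_w = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / (c_out * kernel)), (c_out, c_out, kernel)),
            requires_grad=True,
        )
        self.tconv_b = _Param.zeros(c_out)
        self.bn2 = BatchNorm(c_out)
        self.residual_proj = None
        if c_in != c_out or stride != 1:
            self.residual_proj = _Param.glorot(rng, c_in, c_out)

    def params(self) -> list[Tensor]:
        p = [*self.thetas, self.gcn_bias, self.tconv_w, self.tconv_b]
        p += self.bn1.params() + self.bn2.params() + self.graph.edge_masks
        if self.residual_proj is not None:
            p.append(self.residual_proj)
        return p

    def __call__(
        self, x: Tensor, train: bool, rng: np.random.Generator
    ) -> Tensor:
        B, C, T, V = x.shape
        y = stgcn_spatial(x, self.graph, self.thetas)
        y = y + self.gcn_bias.reshape((1, -1, 1, 1))
        y = self.bn1(y, train).relu()
        # temporal conv with joints folded into the batch
        O = y.shape[1]
        yt = y.transpose((0, 3, 1, 2)).reshape((B * V, O, T))
        pad = _same_ceil_pad(T, self.kernel, self.stride)
        yt = conv1d(yt, self.tconv_w, self.tconv_b, stride=self.stride, pad=pad)
        T_out = yt.shape[2]
        y = yt.reshape((B, V, O, T_out)).transpose((0, 2, 3, 1))
        y = self.bn2(y, train)
        if train and self.dropout > 0:
            mask = (rng.random(y.shape) >= self.dropout) / (1.0 - self.dropout)
            y = y * Tensor(mask)
        # residual path: stride-subsample time, project channels if needed
        res = x[:, :, ::self.stride, :] if self.stride > 1 else x
        if res.shape[2] != T_out:  # ceil padding can add one frame
            res = res[:, :, :T_out, :]
        if self.residual_proj is not None:
            res = (res.transpose((0, 2, 3, 1)) @ self.residual_proj).transpose(
                (0, 3, 1, 2)
            )
        return (y + res).relu()


class _Attention:
    """score = w · tanh(W_v V + W_h H), softmax-normalized along one axis."""

    def __init__(self, rng, feat_dim: int, ctx_dim: int, proj_dim: int, heads: int):
        self.heads = heads
        self.w_v = [_Param.glorot(rng, feat_dim, proj_dim) for _ in range(heads)]
        self.w_h = [_Param.glorot(rng, ctx_dim, proj_dim) for _ in range(heads)]
        self.w_s = [_Param.glorot(rng, proj_dim, 1) for _ in range(heads)]

    def params(self) -> list[Tensor]:
        return [*self.w_v, *self.w_h, *self.w_s]

    def scores(self, feats: Tensor, ctx: Tensor) -> Tensor:
        """feats: (..., N, F); ctx: (B, Ch) broadcast over middle axes.

        Returns raw scores (..., N) averaged over heads.
        """
        out = None
        extra = feats.ndim - 2 - 1  # axes between batch and N
        ctx_shape = (ctx.shape[0],) + (1,) * (extra + 1) + (-1,)
        for wv, wh, ws in zip(self.w_v, self.w_h, self.w_s):
            proj = (feats @ wv + (ctx @ wh).reshape(ctx_shape)).tanh()
            s = (proj @ ws).reshape(feats.shape[:-1])
            out = s if out is None else out + s
        return out * (1.0 / self.heads)


class LSTMCellStack:
    """Single-layer (optionally reversed) LSTM over (B, T, F) inputs."""

    def __init__(self, rng, in_dim: int, hidden: int, reverse: bool = False):
        self.hidden = hidden
        self.reverse = reverse
        self.w_ih = _Param.glorot(rng, in_dim, 4 * hidden)
        self.w_hh = _Param.glorot(rng, hidden, 4 * hidden)
        self.bias = _Param.zeros(4 * hidden)

    def params(self) -> list[Tensor]:
        return [self.w_ih, self.w_hh, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        H = self.hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        steps = range(T - 1, -1, -1) if self.reverse else range(T)
        outs: list[Tensor] = [None] * T  # type: ignore[list-item]
        for t in steps:
            gates = x[:, t, :] @ self.w_ih + h @ self.w_hh + self.bias
            i = gates[:, 0:H].sigmoid()
            f = gates[:, H:2 * H].sigmoid()
            g = gates[:, 2 * H:3 * H].tanh()
            o = gates[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h.reshape((B, 1, H))
        return concatenate(outs, axis=1)  # (B, T, H)


@dataclass
class AssessmentResult:
    """Output of a quality-assessment forward pass."""

    probabilities: np.ndarray     # (B, 4), rows sum to 1
    logits: np.ndarray            # (B, 4)
    quality_score: np.ndarray     # (B,) continuous regression head
    embedding: np.ndarray         # (B, 512)
    spatial_attention: np.ndarray  # (B, T', V)
    temporal_attention: np.ndarray  # (B, T')
    shape_ledger: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)


class AssessmentModel:
    """Enhanced ST-GCN with dual attention for movement-quality assessment."""

    def __init__(
        self,
        cfg: ModelConfig = ModelConfig(),
        graph: GraphSpec | None = None,
        seed: int = 0,
    ):
        self.cfg = cfg
        self.rng = np.random.default_rng(seed)
        self.graph = graph if graph is not None else build_skeleton_graph()
        if self.graph.n_joints != cfg.joints:
            raise ValueError("graph joint count does not match config")
        # per joint-coordinate input normalization (standard ST-GCN data BN):
        # rescales subtle per-joint deviations to a learnable unit scale
        self.data_bn = BatchNorm(cfg.joints * cfg.in_channels)
        self.blocks: list[STGCNBlock] = []
        c_prev = cfg.in_channels
        for c, k, s in cfg.blocks:
            self.blocks.append(
                STGCNBlock(self.rng, self.graph, c_prev, c, k, s, cfg.block_dropout)
            )
            c_prev = c
        c_top = c_prev
        self.spatial_attn = _Attention(
            self.rng, c_top, c_top, max(c_top // 2, 8), cfg.attention_heads
        )
        half = cfg.lstm_units // 2
        self.lstm_fw = LSTMCellStack(self.rng, c_top, half)
        self.lstm_bw = LSTMCellStack(self.rng, c_top, half, reverse=True)
        self.temporal_attn = _Attention(
            self.rng, cfg.lstm_units, cfg.lstm_units,
            max(cfg.lstm_units // 4, 8), cfg.attention_heads,
        )
        self.fc1 = _Param.glorot(self.rng, cfg.lstm_units, cfg.classifier_hidden)
        self.fc1_b = _Param.zeros(cfg.classifier_hidden)
        self.fc2 = _Param.glorot(self.rng, cfg.classifier_hidden, cfg.n_classes)
        self.fc2_b = _Param.zeros(cfg.n_classes)
        self.score_w = _Param.glorot(self.rng, cfg.lstm_units, 1)
        self.score_b = _Param.zeros(1)

    def params(self) -> list[Tensor]:
        p: list[Tensor] = []
        seen: set[int] = set()
        for t in self.data_bn.params():
            seen.add(id(t))
            p.append(t)
        for blk in self.blocks:
            for t in blk.params():
                if id(t) not in seen:
                    seen.add(id(t))
                    p.append(t)
        for t in (
            self.spatial_attn.params()
            + self.lstm_fw.params()
            + self.lstm_bw.params()
            + self.temporal_attn.params()
            + [self.fc1, self.fc1_b, self.fc2, self.fc2_b,
               self.score_w, self.score_b]
        ):
            if id(t) not in seen:
                seen.add(id(t))
                p.append(t)
        return p

    def _check_input(self, x: np.ndarray) -> None:
        cfg = self.cfg
        if x.ndim != 4:
            raise ValueError(f"input must be (batch, joints, channels, frames), got ndim={x.ndim}")
        names = ("batch", "joints", "channels", "frames")
        expect = (None, cfg.joints, cfg.in_channels, cfg.seq_len)
        for ax, (name, want) in enumerate(zip(names, expect)):
            if want is not None and x.shape[ax] != want:
                raise ValueError(
                    f"input dimension '{name}' (axis {ax}) is {x.shape[ax]}, "
                    f"expected {want}"
                )

    def forward(
        self, x: np.ndarray, train: bool = False
    ) -> tuple[Tensor, Tensor, Tensor, dict]:
        """Differentiable forward pass.

        ``x`` is (B, joints, channels, frames).  Returns (logits, embedding,
        score, extras) where extras carries attention tensors, the per-frame
        hidden sequence and the shape ledger.
        """
        self._check_input(np.asarray(x))
        B = x.shape[0]
        ledger = [("input", tuple(x.shape[1:]))]
        # data BN over flattened (joint, coordinate) channels
        V0, C0, T0 = x.shape[1], x.shape[2], x.shape[3]
        h = Tensor(np.asarray(x, dtype=float).reshape(B, V0 * C0, T0))
        h = self.data_bn(h, train)
        # to (B, C, T, V)
        h = h.reshape((B, V0, C0, T0)).transpose((0, 2, 3, 1))
        group_end = {}
        for bi, blk in enumerate(self.blocks):
            h = blk(h, train, self.rng)
            group_end[bi] = h.shape
        # one ledger row per block group (ends where channels or temporal
        # resolution change, and after the final block)
        for bi in range(len(self.blocks)):
            c = self.cfg.blocks[bi][0]
            is_last = bi + 1 == len(self.cfg.blocks)
            if not is_last:
                c_next, _, s_next = self.cfg.blocks[bi + 1]
                if c_next == c and s_next == 1:
                    continue
            _, C, T, V = group_end[bi]
            ledger.append((f"stgcn_group_{c}ch", (V, C, T)))
        B_, C, T, V = h.shape
        # ---- spatial attention over joints, per frame
        feats = h.transpose((0, 2, 3, 1))  # (B, T, V, C)
        ctx = h.mean(axis=(2, 3))          # (B, C)
        s_scores = self.spatial_attn.scores(feats, ctx)  # (B, T, V)
        alpha_s = s_scores.softmax(axis=2)
        attn_w = alpha_s
        if train and self.cfg.attention_dropout > 0:
            keep = (
                self.rng.random(alpha_s.shape) >= self.cfg.attention_dropout
            ) / (1.0 - self.cfg.attention_dropout)
            attn_w = alpha_s * Tensor(keep)
        # reweight joints; x V so uniform attention is the identity map
        h = h * attn_w.reshape((B_, 1, T, V)) * float(V)
        ledger.append(("spatial_attention", (V, C, T)))
        # ---- per-joint bidirectional LSTM over time
        seq = h.transpose((0, 3, 2, 1)).reshape((B_ * V, T, C))
        hid = concatenate([self.lstm_fw(seq), self.lstm_bw(seq)], axis=2)
        U = self.cfg.lstm_units
        hid = hid.reshape((B_, V, T, U))
        ledger.append(("temporal_attention_lstm", (V, U, T)))
        # ---- temporal attention over frames on the joint-pooled sequence
        g = hid.mean(axis=1)  # (B, T, U)
        t_ctx = g.mean(axis=1)  # (B, U)
        t_scores = self.temporal_attn.scores(g, t_ctx)  # (B, T)
        alpha_t = t_scores.softmax(axis=1)
        # ---- attention-weighted global pooling -> 512-d embedding
        emb = (g * alpha_t.reshape((B_, T, 1))).sum(axis=1)  # (B, U)
        ledger.append(("global_pooling", (U,)))
        hidden = (emb @ self.fc1 + self.fc1_b).relu()
        logits = hidden @ self.fc2 + self.fc2_b
        score = (emb @ self.score_w + self.score_b).reshape((B_,))
        ledger.append(("classifier", (self.cfg.n_classes,)))
        extras = {
            "alpha_s": alpha_s,
            "alpha_t": alpha_t,
            "hidden_seq": g,
            "shape_ledger": ledger,
        }
        return logits, emb, score, extras

    def assess(self, x: np.ndarray) -> AssessmentResult:
        """Evaluation-mode assessment of a batch of sequences."""
        with no_grad():
            logits, emb, score, extras = self.forward(x, train=False)
        probs = _softmax_np(logits.data)
        return AssessmentResult(
            probabilities=probs,
            logits=logits.data,
            quality_score=score.data,
            embedding=emb.data,
            spatial_attention=extras["alpha_s"].data,
            temporal_attention=extras["alpha_t"].data,
            shape_ledger=extras["shape_ledger"],
        )

    def calibrate_norm(self, items: np.ndarray) -> None:
        """Recompute batch-norm running statistics from a reference set.

        One forward pass in training mode with momentum 0 replaces the
        running mean/variance of every norm layer with the exact
        statistics of ``items`` — removes the train/eval statistics lag
        that batch norm suffers on small datasets.
        """
        norms = self.norm_layers()
        saved = [(n.momentum, n.freeze_stats) for n in norms]
        for n in norms:
            n.momentum = 0.0
            n.freeze_stats = False
        # dropout must stay off: scale-compensated masks would bias stats
        drops = [(blk, blk.dropout) for blk in self.blocks]
        for blk, _ in drops:
            blk.dropout = 0.0
        attn_drop = self.cfg.attention_dropout
        object.__setattr__(self.cfg, "attention_dropout", 0.0)
        try:
            with no_grad():
                self.forward(items, train=True)
        finally:
            for n, (m, fz) in zip(norms, saved):
                n.momentum = m
                n.freeze_stats = fz
            for blk, d in drops:
                blk.dropout = d
            object.__setattr__(self.cfg, "attention_dropout", attn_drop)

    def norm_layers(self) -> list[BatchNorm]:
        norms = [self.data_bn]
        for blk in self.blocks:
            norms += [blk.bn1, blk.bn2]
        return norms

    def set_norm_frozen(self, frozen: bool) -> None:
        for n in self.norm_layers():
            n.freeze_stats = frozen

    # ---- checkpointing ---------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params()]

    def save(self, path: str) -> None:
        import json

        arrays = {f"p{i}": a for i, a in enumerate(self.state_arrays())}
        cfg_json = json.dumps(self.cfg.__dict__, default=list)
        np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "AssessmentModel":
        import json

        with np.load(path) as data:
            cfg_json = bytes(data["__config__"]).decode()
            raw = json.loads(cfg_json)
            raw["blocks"] = tuple(tuple(b) for b in raw["blocks"])
            model = cls(ModelConfig(**raw))
            for i, p in enumerate(model.params()):
                p.data[...] = data[f"p{i}"]
        return model


def reduced_model_config() -> ModelConfig:
    """CPU-scale model preset: same topology as the default architecture
    (three block groups with strides 1/2/2, dual attention, BiLSTM) at a
    fraction of the width, suitable for desk-scale training."""
    return ModelConfig(
        blocks=((16, 9, 1), (32, 9, 2), (32, 9, 2)),
        attention_heads=2,
        lstm_units=64,
        classifier_hidden=64,
    )


def _softmax_np(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)
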