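"""Skeleton graph construction for spatio-temporal graph convolution.

The joint graph uses a three-partition strategy: (1) *physical* —
symmetric adjacency along skeleton bones, (2) *centripetal* — directed
edges from limb joints toward the torso root, and (3) *temporal-self* —
the identity, the spatial face of same-joint-across-frames connectivity
(the temporal kernel handles the rest).  Each partition carries a
learnable edge-importance mask M_k, applied elementwise to the
degree-normalized adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from taijikit.autodiff import Tensor
from taijikit.layout import JOINT_NAMES_32, parents, skeleton_edges

__all__ = ["GraphSpec", "build_skeleton_graph"]


def _degree_normalize(a: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^-1/2 A D^-1/2 (zero-degree safe)."""
    deg = a.sum(axis=1)
    d = np.zeros_like(deg)
    nz = deg > 0
    d[nz] = deg[nz] ** -0.5
    return d[:, None] * a * d[None, :]


@dataclass
class GraphSpec:
    """K_s adjacency partitions with learnable edge-importance masks."""

    adjacency_partitions: list[np.ndarray]
    partition_kinds: tuple[str, ...]
    normalize: bool = True
    edge_masks: list[Tensor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.adjacency_partitions) < 1:
            raise ValueError("need at least one adjacency partition")
        V = self.adjacency_partitions[0].shape[0]
        for a in self.adjacency_partitions:
            if a.shape != (V, V):
                raise ValueError("all partitions must be square and same size")
            if np.any(a < 0):
                raise ValueError("adjacency entries must be nonnegative")
        for kind, a in zip(self.partition_kinds, self.adjacency_partitions):
            if kind == "physical" and not np.allclose(a, a.T):
                raise ValueError("physical partition must be symmetric")
        if self.normalize:
            self.normalized = [_degree_normalize(a) for a in self.adjacency_partitions]
        else:
            self.normalized = [a.copy() for a in self.adjacency_partitions]
        if not self.edge_masks:
            self.edge_masks = [
                Tensor(np.ones((V, V)), requires_grad=True)
                for _ in self.adjacency_partitions
            ]

    @property
    def n_joints(self) -> int:
        return self.adjacency_partitions[0].shape[0]

    @property
    def k_s(self) -> int:
        return len(self.adjacency_partitions)

    def effective(self, k: int) -> Tensor:
        """(A_k normalized) ⊙ M_k as a differentiable tensor."""
        return self.edge_masks[k] * Tensor(self.normalized[k])


def build_skeleton_graph(
    joint_names: tuple[str, ...] = JOINT_NAMES_32,
) -> GraphSpec:
    """Three-partition graph for a canonical skeleton layout."""
    V = len(joint_names)
    phys = np.zeros((V, V))
    for i, j in skeleton_edges(joint_names):
        phys[i, j] = phys[j, i] = 1.0
    centripetal = np.zeros((V, V))
    for c, p in enumerate(parents(joint_names)):
        if p >= 0:
            centripetal[p, c] = 1.0  # aggregate child info toward the torso
    temporal_self = np.eye(V)
    return GraphSpec(
        adjacency_partitions=[phys, centripetal, temporal_self],
        partition_kinds=("physical", "centripetal", "temporal-self"),
    )
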